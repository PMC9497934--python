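"""Independent closed-form/quadrature oracles shared by the test modules.

These are deliberately written against the *physics* (error-function edge
profiles, Gauss-Legendre aperture integration) rather than against any code
path they are used to check.
"""

import numpy as np
from scipy.special import ndtr, roots_legendre


def edge_esf_oracle(d, pitch, angle_deg, sigma, contrast=1.0, order=32):
    """Aperture-averaged blurred-step profile at center distance ``d`` (mm).

    The Gaussian-blurred half-plane step is an error-function ramp along the
    edge normal; the square pixel aperture (tilted ``angle_deg`` relative to
    the edge) is integrated by tensor-product Gauss-Legendre quadrature.
    """
    theta = np.radians(angle_deg)
    nodes, weights = roots_legendre(order)
    u = nodes * pitch / 2.0
    w = weights / 2.0
    delta = (u[:, None] * np.cos(theta) - u[None, :] * np.sin(theta)).ravel()
    wgt = np.outer(w, w).ravel()
    vals = np.asarray(d, dtype=float)[..., None] + delta
    ramp = ndtr(vals / sigma) if sigma > 0 else (vals > 0).astype(float)
    profile = (1 - contrast) + contrast * ramp
    return (profile * wgt).sum(axis=-1)
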