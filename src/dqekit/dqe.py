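"""Detective quantum efficiency: combining MTF, NNPS and photon statistics.

    DQE(f) = SNR_out^2 / SNR_in^2 = MTF^2(f) / (Ka * (SNR^2/Ka) * NNPS(f))

with ``Ka`` the measured air kerma (uGy) and ``SNR^2/Ka`` the beam quality's
squared SNR per air kerma — numerically the photon fluence per air kerma
ratio — so the denominator is the input photon fluence ``Phi`` (mm^-2) times
the NNPS (mm^2), making the DQE dimensionless and confined to [0, 1] for an
ideal estimator.  NNPS enters to the first power.
"""

from __future__ import annotations

import warnings

import numpy as np

from .curves import DQECurve, MTFCurve, NNPSCurve
from .exceptions import ConfigError, NormalizationError
from .protocols import BeamQuality

__all__ = ["compute_dqe"]


def compute_dqe(mtf: MTFCurve, nnps: NNPSCurve, bq: BeamQuality,
                kerma: float) -> DQECurve:
    """Compute the DQE curve at a stated beam quality and air kerma.

    The two input curves are resampled by linear interpolation onto the
    coarser of the two frequency grids, restricted to the overlap of their
    supports (no extrapolation).  Sampling noise can push individual bins
    slightly above 1; values are reported unclipped with a warning.
    """
    if kerma <= 0:
        raise ConfigError(f"air kerma must be > 0, got {kerma}")
    if len(mtf) < 2 or len(nnps) < 2:
        raise ConfigError("MTF and NNPS curves must have >= 2 samples")
    step_mtf = np.min(np.diff(mtf.frequencies))
    step_nnps = np.min(np.diff(nnps.frequencies))
    coarser = mtf if step_mtf >= step_nnps else nnps
    lo = max(mtf.frequencies[0], nnps.frequencies[0])
    hi = min(mtf.frequencies[-1], nnps.frequencies[-1])
    if hi <= lo:
        raise ConfigError("MTF and NNPS frequency supports do not overlap")
    grid = coarser.frequencies[(coarser.frequencies >= lo - 1e-12)
                               & (coarser.frequencies <= hi + 1e-12)]
    mtf_v = mtf.interp(grid)
    nnps_v = nnps.interp(grid)
    if np.any(nnps_v == 0):
        f_bad = grid[np.nonzero(nnps_v == 0)[0][0]]
        raise NormalizationError(
            f"NNPS is zero at {f_bad:g} lp/mm; DQE undefined there")
    fluence = kerma * bq.snr2_per_kerma
    values = mtf_v**2 / (fluence * nnps_v)
    if np.any(values > 1):
        warnings.warn(
            "DQE exceeds 1 in some bins (sampling noise); values reported "
            "unclipped", stacklevel=2)
    return DQECurve(frequencies=grid, values=values, kerma=kerma, beam=bq.name)
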