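"""Degradation and restoration of blurred, noisy radiographs.

Degradation model: ``h = PSF ** f + n`` where ``**`` is 2-D convolution,
the PSF describes the system blur (scintillator thickness, focal spot,
pixel aperture) and ``n`` is additive noise lumping quantum and electronic
components.  Restoration follows the denoise-then-deconvolve workflow: an
adaptive local minimum-mean-square filter suppresses the noise, a point
spread function synthesized from the measured 1-D MTF defines the transfer
to invert, and a Wiener filter performs the deconvolution.  Deconvolution is
akin to high-pass filtering, so some noise amplification is unavoidable —
hence the pre-filtering stage and the ``nsr`` regularizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, uniform_filter

from .curves import MTFCurve
from .exceptions import ConfigError, NormalizationError
from .frames import ImageFrame

__all__ = [
    "DegradationModel",
    "degrade",
    "denoise_adaptive",
    "psf_from_mtf",
    "wiener_deconvolve",
]


@dataclass
class DegradationModel:
    """Blur kernel plus additive noise level.

    psf : 2-D non-negative kernel, unit sum (tolerance 1e-6).
    noise_sigma : standard deviation of the additive Gaussian noise, in
        signal units.
    """

    psf: np.ndarray
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.psf = np.asarray(self.psf, dtype=float)
        if self.psf.ndim != 2:
            raise ConfigError("PSF must be 2-D")
        if np.any(self.psf < 0):
            raise ConfigError("PSF values must be >= 0")
        if abs(self.psf.sum() - 1.0) > 1e-6:
            raise ConfigError(
                f"PSF must sum to 1 +- 1e-6, got {self.psf.sum():.8f}")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")


def degrade(image: ImageFrame, model: DegradationModel,
            seed: int = 0) -> ImageFrame:
    """Apply the degradation model: blur (reflective boundary) plus noise."""
    if (model.psf.shape[0] > image.shape[0]
            or model.psf.shape[1] > image.shape[1]):
        raise ConfigError("PSF must be smaller than the image")
    blurred = convolve(image.pixels.astype(float), model.psf, mode="reflect")
    if model.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        blurred = blurred + rng.normal(0.0, model.noise_sigma, blurred.shape)
    return ImageFrame(pixels=blurred, pixel_pitch=image.pixel_pitch)


def denoise_adaptive(image: ImageFrame, window: int = 5,
                     noise_var: float | None = None) -> ImageFrame:
    """Adaptive local minimum-mean-square (Wiener-type) denoising.

    Per pixel, with local mean ``m`` and local variance ``v`` over a
    ``window x window`` neighbourhood:

        out = m + max(0, v - nv) / max(v, nv) * (in - m)

    so flat regions collapse to their local mean while structured regions
    pass through.  ``noise_var=None`` estimates the noise variance as the
    median of the local variances.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigError(f"window must be odd and >= 3, got {window}")
    x = image.pixels.astype(float)
    m = uniform_filter(x, window, mode="reflect")
    m2 = uniform_filter(x * x, window, mode="reflect")
    v = np.maximum(m2 - m * m, 0.0)
    nv = float(np.median(v)) if noise_var is None else float(noise_var)
    if nv < 0:
        raise ConfigError("noise_var must be >= 0")
    if nv == 0:
        return ImageFrame(pixels=x.copy(), pixel_pitch=image.pixel_pitch)
    gain = np.maximum(v - nv, 0.0) / np.maximum(v, nv)
    out = m + gain * (x - m)
    return ImageFrame(pixels=out, pixel_pitch=image.pixel_pitch)


def _radial_transfer(curve: MTFCurve, radius: np.ndarray) -> np.ndarray:
    """Evaluate a 1-D MTF radially, continuing its tail beyond the support.

    Frequencies past the last curve sample (grid corners) follow a
    log-linear continuation of the curve's final decade, so a near-Gaussian
    tail keeps decaying instead of being clamped.
    """
    f = curve.frequencies
    v = np.clip(curve.values, 0.0, None)
    h = np.interp(radius, f, v)
    beyond = radius > f[-1]
    if np.any(beyond) and v[-1] > 0:
        # continue the tail with a log-quadratic roll-off fitted to the last
        # usable samples (exact for a Gaussian transfer, smooth otherwise)
        usable = np.nonzero(v > 1e-9)[0]
        if usable.size >= 3 and usable[-1] == f.size - 1:
            tail = usable[-min(usable.size, 8):]
            design = np.stack([np.ones(tail.size), f[tail] ** 2], axis=1)
            coef, *_ = np.linalg.lstsq(design, np.log(v[tail]), rcond=None)
            decay = min(coef[1], 0.0)
            rb = radius[beyond]
            h[beyond] = v[-1] * np.exp(decay * (rb**2 - f[-1] ** 2))
        else:
            h[beyond] = 0.0
    elif np.any(beyond):
        h[beyond] = 0.0
    return h


def psf_from_mtf(curve: MTFCurve, pitch: float, support: int = 15) -> np.ndarray:
    """Synthesize a radially symmetric PSF kernel from a measured 1-D MTF.

    The 1-D curve is swept into a 2-D radially symmetric transfer magnitude
    on the kernel's frequency grid, inverse-transformed, clipped at zero,
    truncated to ``support x support`` pixels and renormalized to unit sum.
    """
    if support % 2 == 0 or support < 3:
        raise ConfigError(f"support must be odd and >= 3, got {support}")
    if np.any(np.asarray(curve.values) < -1e-3):
        raise ConfigError("MTF curve has significantly negative values")
    if curve.frequencies[-1] < 1.0 / (2.0 * pitch) - 1e-9:
        raise ConfigError("MTF curve must extend to the detector Nyquist")
    freqs = np.fft.fftfreq(support, d=pitch)
    # The DTFT of the *sampled* PSF is the alias-folded continuous transfer;
    # folding the spectral replicas (tail continued past Nyquist by
    # _radial_transfer) makes the inverse transform the PSF sampled at pixel
    # centers rather than its band-limited, ringing-prone interpolant.
    h = np.zeros((support, support))
    for j in (-1, 0, 1):
        for k in (-1, 0, 1):
            radius = np.hypot(freqs[None, :] - j / pitch,
                              freqs[:, None] - k / pitch)
            h += _radial_transfer(curve, radius)
    kernel = np.fft.fftshift(np.real(np.fft.ifft2(h)))
    kernel = np.clip(kernel, 0.0, None)
    total = kernel.sum()
    if total == 0:
        raise NormalizationError("synthesized PSF has zero mass")
    return kernel / total


def wiener_deconvolve(image: ImageFrame, curve: MTFCurve,
                      nsr: float = 1e-2, pad: int = 32) -> ImageFrame:
    """Wiener deconvolution with the transfer synthesized from a 1-D MTF.

    Applies ``W = H / (H^2 + nsr)`` in the frequency domain (H real and
    non-negative from the radially swept curve), with symmetric padding to
    suppress wrap-around ringing.  The zero-frequency gain is pinned to 1 so
    the image mean is preserved.  ``nsr`` is the scalar noise-to-signal
    power ratio; larger values regularize more.
    """
    if nsr < 0:
        raise ConfigError(f"nsr must be >= 0, got {nsr}")
    x = np.pad(image.pixels.astype(float), pad, mode="symmetric")
    fu = np.fft.fftfreq(x.shape[1], d=image.pixel_pitch)
    fv = np.fft.fftfreq(x.shape[0], d=image.pixel_pitch)
    radius = np.hypot(fu[None, :], fv[:, None])
    h = _radial_transfer(curve, radius)
    if nsr == 0 and np.any(h == 0):
        raise ConfigError(
            "nsr = 0 with zero-valued transfer bins: inversion ill-posed")
    w = h / (h**2 + nsr) if nsr > 0 else 1.0 / h
    w.flat[0] = 1.0  # preserve the mean exactly
    out = np.real(np.fft.ifft2(np.fft.fft2(x) * w))
    out = out[pad:pad + image.shape[0], pad:pad + image.shape[1]]
    return ImageFrame(pixels=out, pixel_pitch=image.pixel_pitch)
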