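"""Forward model of an indirect-conversion flat-panel imaging chain.

The simulator produces flat-field ("white") frames, tilted-edge images and
disc contrast phantoms whose MTF and NNPS are known in closed form, so every
estimator in the toolkit can be verified without detector hardware.

Physical model, per pixel of pitch ``a`` (mm):

1. X-ray quanta arrive as a Poisson process of fluence ``q`` photons/mm^2
   (optionally derived from a beam quality and air kerma via the registry).
2. The scintillator spreads the signal with an isotropic Gaussian point
   spread function of standard deviation ``blur_sigma`` (mm).
3. The pixel aperture integrates the blurred field over its ``a x a`` area.
4. The readout applies a linear ``gain`` (output units per detected photon)
   and adds white Gaussian electronic noise of ``electronic_sigma`` output
   units.

Ground truth:

* presampled MTF:  ``exp(-2 pi^2 sigma^2 f^2) * |sinc(pi a f)|``
  (Gaussian blur times pixel aperture), see :func:`theoretical_mtf`;
* NNPS: quantum term shaped by the squared blur/aperture transfer summed
  over its spectral replicas (sampling aliases the presampled quantum noise
  back into the Nyquist band), plus a flat electronic term, both normalized
  by the squared mean signal, see :func:`theoretical_nnps`.

Mean signal fields are rendered analytically (error-function edge profiles
integrated over the pixel aperture by high-order supersampling).  Quantum
noise is exact Poisson for unblurred chains; blurred chains draw a Gaussian
random field synthesized spectrally with the exact target noise power
spectrum (blurred pixel counts pool many Poisson contributions, so the
Gaussian limit holds to high accuracy at radiographic fluences), which
reproduces the correlation the scintillator blur imposes on the noise.

Determinism: one master ``seed``; every frame draws from an independent
substream derived from (seed, stream, frame index), so identical configs
produce bit-identical frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr

from .exceptions import ConfigError, LayoutError, NormalizationError
from .frames import ImageFrame, ROIRect
from .protocols import fluence_from_kerma, get_beam_quality, get_detector_spec

__all__ = [
    "ChainConfig",
    "PhantomLayout",
    "simulate_flat_field",
    "simulate_edge_image",
    "simulate_phantom",
    "theoretical_mtf",
    "theoretical_nnps",
    "theoretical_nnps_2d",
    "illustrative_chain_config",
    "ILLUSTRATIVE_PRESETS",
]


@dataclass(frozen=True)
class ChainConfig:
    """Ground-truth parameters of the simulated imaging chain.

    Parameters
    ----------
    fluence : float
        Photon fluence at the detector entrance, photons/mm^2.
    pixel_pitch : float
        Pixel pitch in mm.
    blur_sigma : float
        Scintillator Gaussian blur sigma in mm (0 disables blur).
    gain : float
        Output units per detected photon.
    electronic_sigma : float
        Additive white Gaussian readout noise, output units.
    frame_shape : (rows, cols)
        Frame dimensions in pixels.
    seed : int
        Master seed of the frame-substream hierarchy.
    quantum_noise : bool
        If False the Poisson stage is skipped and the noiseless mean field
        is returned (electronic noise still applies if nonzero).
    noise_supersample : int
        Sub-pixel rendering factor for aperture integration of non-analytic
        mean fields (phantom discs).
    gaussian_approx_threshold : float
        Poisson means above this are drawn from the matching normal
        distribution (speed; relative error < 1/sqrt(threshold)).
    """

    fluence: float
    pixel_pitch: float
    blur_sigma: float = 0.0
    gain: float = 1.0
    electronic_sigma: float = 0.0
    frame_shape: tuple[int, int] = (512, 512)
    seed: int = 0
    quantum_noise: bool = True
    noise_supersample: int = 4
    gaussian_approx_threshold: float = 1000.0

    def __post_init__(self) -> None:
        if self.fluence < 0:
            raise ConfigError(f"fluence must be >= 0, got {self.fluence}")
        if not (self.pixel_pitch > 0):
            raise ConfigError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")
        if self.blur_sigma < 0 or self.electronic_sigma < 0:
            raise ConfigError("blur_sigma and electronic_sigma must be >= 0")
        rows, cols = self.frame_shape
        if rows <= 0 or cols <= 0:
            raise ConfigError(f"frame_shape must be positive, got {self.frame_shape}")
        if self.noise_supersample < 1:
            raise ConfigError("noise_supersample must be >= 1")

    @property
    def mean_counts_per_pixel(self) -> float:
        return self.fluence * self.pixel_pitch**2

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel_pitch)


@dataclass(frozen=True)
class PhantomLayout:
    """Disc-on-background contrast phantom description.

    discs : list of ``((x, y), radius, contrast)`` in pixel units; inside a
        disc the transmitted fluence is reduced by the contrast fraction.
    roi_pairs : list of ``(roi_in_disc, roi_on_background)`` used for CNR.
    background_level : transmission of the open background (fraction of the
        incident fluence, default 1.0).
    """

    discs: tuple = ()
    roi_pairs: tuple = ()
    background_level: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.background_level <= 1):
            raise LayoutError("background_level must be in (0, 1]")
        for (cx, cy), radius, contrast in self.discs:
            if radius <= 0:
                raise LayoutError("disc radius must be > 0")
            if not (0 <= contrast <= 1):
                raise LayoutError("disc contrast must be in [0, 1]")
        for roi_a, roi_b in self.roi_pairs:
            if roi_a.overlaps(roi_b):
                raise LayoutError(f"ROI pair overlaps: {roi_a} / {roi_b}")

    def validate_for_shape(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        for (cx, cy), radius, _ in self.discs:
            if (cx - radius < 0 or cy - radius < 0
                    or cx + radius > cols or cy + radius > rows):
                raise LayoutError(
                    f"disc at ({cx}, {cy}) r={radius} lies outside "
                    f"frame {rows}x{cols}")
        for roi_a, roi_b in self.roi_pairs:
            roi_a.validate_within(shape)
            roi_b.validate_within(shape)


# ----------------------------------------------------------------------------
# random sampling helpers

def _rng(cfg: ChainConfig, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, stream, index])


def _poisson(rng: np.random.Generator, mean: np.ndarray,
             threshold: float) -> np.ndarray:
    """Poisson counts with a normal approximation above ``threshold``."""
    mean = np.asarray(mean, dtype=float)
    lo = float(mean.min()) if mean.size else 0.0
    hi = float(mean.max()) if mean.size else 0.0
    if lo > threshold:
        return rng.normal(mean, np.sqrt(mean))
    if hi <= threshold:
        return rng.poisson(mean).astype(float)
    big = mean > threshold
    out = np.empty_like(mean)
    out[~big] = rng.poisson(mean[~big])
    out[big] = rng.normal(mean[big], np.sqrt(mean[big]))
    return out


def _block_sum(arr: np.ndarray, s: int) -> np.ndarray:
    rows, cols = arr.shape
    return arr.reshape(rows // s, s, cols // s, s).sum(axis=(1, 3))


def _stationary_quantum_noise(cfg: ChainConfig, rng: np.random.Generator,
                              shape: tuple[int, int]) -> np.ndarray:
    """Zero-mean quantum noise of a blurred chain, in detected counts.

    For a blurred chain the pixel counts are weighted sums of many Poisson
    contributions, so the quantum noise is Gaussian to excellent accuracy;
    it is synthesized spectrally with the *exact* target power spectrum
    ``q a^4 T(u) T(v)`` (the aliased blur/aperture transfer of
    :func:`theoretical_nnps_2d`), which reproduces both the per-pixel
    variance and the correlation the scintillator blur imposes without the
    transfer bias a discretized blur-and-bin chain would introduce.
    """
    rows, cols = shape
    a = cfg.pixel_pitch
    fu = np.abs(np.fft.fftfreq(cols, d=a))
    fv = np.abs(np.fft.fftfreq(rows, d=a))
    tu = _aliased_quantum_transfer(fu, cfg.blur_sigma, a)
    tv = _aliased_quantum_transfer(fv, cfg.blur_sigma, a)
    amp = math.sqrt(cfg.fluence) * a * np.sqrt(np.outer(tv, tu))
    white = rng.standard_normal(shape)
    # Hermitian symmetry of fft2(white) is preserved by the real symmetric
    # amplitude, so the inverse transform is exactly real
    return np.real(np.fft.ifft2(np.fft.fft2(white) * amp))


def _readout(cfg: ChainConfig, counts: np.ndarray,
             rng: np.random.Generator) -> ImageFrame:
    pixels = cfg.gain * counts
    if cfg.electronic_sigma > 0:
        pixels = pixels + rng.normal(0.0, cfg.electronic_sigma, counts.shape)
    return ImageFrame(pixels=pixels, pixel_pitch=cfg.pixel_pitch)


# ----------------------------------------------------------------------------
# flat fields

def simulate_flat_field(cfg: ChainConfig, n_frames: int = 1) -> list[ImageFrame]:
    """Simulate uniform-exposure frames.

    Each pixel is ``gain * (blurred Poisson count of mean fluence*pitch^2)``
    plus electronic noise; frames are independent given sub-seeds derived
    deterministically from the master seed.
    """
    if n_frames < 1:
        raise ConfigError(f"n_frames must be >= 1, got {n_frames}")
    rows, cols = cfg.frame_shape
    mu = cfg.mean_counts_per_pixel
    frames = []
    for i in range(n_frames):
        rng = _rng(cfg, 0, i)
        counts = np.full((rows, cols), mu)
        if cfg.quantum_noise and mu > 0:
            if cfg.blur_sigma > 0:
                counts = counts + _stationary_quantum_noise(cfg, rng,
                                                            (rows, cols))
            else:
                counts = _poisson(rng, counts, cfg.gaussian_approx_threshold)
        frames.append(_readout(cfg, counts, rng))
    return frames


# ----------------------------------------------------------------------------
# tilted edge

def _edge_distance_grid(shape: tuple[int, int], pitch: float, angle_deg: float,
                        supersample: int = 1) -> np.ndarray:
    """Signed distance (mm) from each (sub-)pixel center to the edge line.

    The edge passes through the frame center, tilted ``angle_deg`` from the
    pixel-column axis; positive distances are on the bright side.
    """
    rows, cols = shape
    theta = math.radians(angle_deg)
    step = pitch / supersample
    x = (np.arange(cols * supersample) + 0.5) * step - cols * pitch / 2.0
    y = (np.arange(rows * supersample) + 0.5) * step - rows * pitch / 2.0
    return (x[None, :] * math.cos(theta) - y[:, None] * math.sin(theta))


def _blurred_step(d: np.ndarray, sigma: float, contrast: float) -> np.ndarray:
    """Transmission profile across the edge after Gaussian blur.

    A 2-D Gaussian blur of a half-plane step is an error-function ramp along
    the edge normal: ``(1 - c) + c * Phi(d / sigma)``.
    """
    if sigma > 0:
        ramp = ndtr(d / sigma)
    else:
        ramp = np.where(d > 0, 1.0, np.where(d < 0, 0.0, 0.5))
    return (1.0 - contrast) + contrast * ramp


def _edge_mean_transmission(shape: tuple[int, int], pitch: float,
                            angle_deg: float, contrast: float, sigma: float,
                            aperture_supersample: int = 16) -> np.ndarray:
    """Pixel-aperture average of the blurred edge transmission (analytic).

    The blurred profile is exact (error function); the aperture integral is
    evaluated by midpoint supersampling (default 16x16 per pixel).  Pixels far
    from the edge take their flat plateau values exactly.
    """
    ss = aperture_supersample
    if ss < 8:
        raise ConfigError("aperture supersampling must be >= 8 per axis")
    theta = math.radians(angle_deg)
    d_center = _edge_distance_grid(shape, pitch, angle_deg)
    # far-field plateau values
    t = np.where(d_center > 0, 1.0, 1.0 - contrast)
    halfwidth = 4.0 * sigma + pitch
    band = np.abs(d_center) <= halfwidth
    if np.any(band):
        offs = ((np.arange(ss) + 0.5) / ss - 0.5) * pitch
        deltas = (offs[:, None] * math.cos(theta)
                  - offs[None, :] * math.sin(theta)).ravel()
        d_band = d_center[band]
        acc = np.zeros_like(d_band)
        for delta in deltas:
            acc += _blurred_step(d_band + delta, sigma, contrast)
        t[band] = acc / deltas.size
    return t


def simulate_edge_image(cfg: ChainConfig, angle: float,
                        edge_contrast: float = 1.0,
                        aperture_supersample: int = 16) -> ImageFrame:
    """Simulate a radiograph of a straight edge tilted ``angle`` degrees.

    The edge passes through the frame center, tilted from the pixel-column
    axis; the dark side transmits ``1 - edge_contrast`` of the fluence
    (default 1.0: an opaque tungsten foil).  Blur, aperture integration and
    noise follow the flat-field chain.
    """
    if not (0 < angle < 45):
        raise ConfigError(f"edge angle must be in (0, 45) degrees, got {angle}")
    if not (0 < edge_contrast <= 1):
        raise ConfigError(
            f"edge_contrast must be in (0, 1], got {edge_contrast}")
    rows, cols = cfg.frame_shape
    t_mean = _edge_mean_transmission(cfg.frame_shape, cfg.pixel_pitch, angle,
                                     edge_contrast, cfg.blur_sigma,
                                     aperture_supersample)
    mean_pix = cfg.mean_counts_per_pixel * t_mean
    rng = _rng(cfg, 1, 0)
    counts = mean_pix
    if cfg.quantum_noise and cfg.fluence > 0:
        if cfg.blur_sigma > 0:
            # stationary correlated quantum noise at the bright-side fluence,
            # modulated by the local transmitted fraction (Poisson variance
            # scales with the local mean; the modulation band is only a few
            # blur widths wide so the correlation structure is preserved)
            noise = _stationary_quantum_noise(cfg, rng, (rows, cols))
            counts = mean_pix + np.sqrt(t_mean) * noise
        else:
            counts = _poisson(rng, mean_pix, cfg.gaussian_approx_threshold)
    return _readout(cfg, counts, rng)


# ----------------------------------------------------------------------------
# contrast phantom

def simulate_phantom(cfg: ChainConfig, layout: PhantomLayout,
                     supersample: int | None = None) -> ImageFrame:
    """Simulate a disc-on-background contrast phantom.

    Discs modulate the fluence (fraction ``1 - contrast`` inside each disc)
    before blur and noise, so ROI statistics on the result follow the same
    Poisson/Gaussian chain as the flat fields.
    """
    layout.validate_for_shape(cfg.frame_shape)
    rows, cols = cfg.frame_shape
    s = supersample or max(cfg.noise_supersample, 2)
    # transmission on the sub-pixel grid (pixel units)
    x = (np.arange(cols * s) + 0.5) / s
    y = (np.arange(rows * s) + 0.5) / s
    t_sub = np.full((rows * s, cols * s), layout.background_level)
    for (cx, cy), radius, contrast in layout.discs:
        mask = ((x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2) <= radius**2
        t_sub[mask] *= (1.0 - contrast)
    mean_sub = cfg.fluence * (cfg.pixel_pitch / s) ** 2 * t_sub
    if cfg.blur_sigma > 0:
        sigma_cells = cfg.blur_sigma / (cfg.pixel_pitch / s)
        mean_sub = gaussian_filter(mean_sub, sigma_cells, mode="reflect")
    mean_pix = _block_sum(mean_sub, s)
    rng = _rng(cfg, 2, 0)
    counts = mean_pix
    if cfg.quantum_noise and cfg.fluence > 0:
        if cfg.blur_sigma > 0:
            noise = _stationary_quantum_noise(cfg, rng, cfg.frame_shape)
            rel = mean_pix / cfg.mean_counts_per_pixel
            counts = mean_pix + np.sqrt(rel) * noise
        else:
            counts = _poisson(rng, mean_pix, cfg.gaussian_approx_threshold)
    return _readout(cfg, counts, rng)


# ----------------------------------------------------------------------------
# closed-form ground truth

def theoretical_mtf(cfg: ChainConfig, f: np.ndarray | float) -> np.ndarray:
    """Presampled MTF of the simulated chain at frequency ``f`` (lp/mm).

    ``MTF(f) = exp(-2 pi^2 sigma^2 f^2) * |sinc(pi * pitch * f)|``
    (Gaussian scintillator blur times the pixel-aperture sinc), equal to 1 at
    f = 0 by construction.
    """
    f = np.asarray(f, dtype=float)
    blur = np.exp(-2.0 * np.pi**2 * cfg.blur_sigma**2 * f**2)
    aperture = np.abs(np.sinc(cfg.pixel_pitch * f))
    return blur * aperture


def _aliased_quantum_transfer(f: np.ndarray, sigma: float,
                              pitch: float) -> np.ndarray:
    """Axis transfer of sampled quantum noise (aliases folded in exactly).

    The presampled quantum noise spectrum is shaped by the squared blur and
    aperture transfer ``|G(f)|^2 sinc^2(pi p f)``; sampling at pitch ``p``
    folds every spectral replica back into the Nyquist band.  Rather than
    truncating the slowly converging replica sum, the transfer is computed
    exactly as the DTFT of the pixel-count autocovariance: lag ``j`` of the
    per-axis covariance is the overlap integral of two blur-smeared pixel
    apertures, a triangle of base ``2p`` convolved with a Gaussian of width
    ``sigma * sqrt(2)``.  With no blur the transfer is exactly 1 at every
    frequency (sampled white noise).
    """
    f = np.asarray(f, dtype=float)
    if sigma == 0:
        return np.ones_like(f)
    p = pitch
    s2 = sigma * math.sqrt(2.0)
    jmax = int(math.ceil((6.0 * s2 + 2.0 * p) / p))
    # k(j) = integral of (p - |t|)+ * gauss_{s2}(j p - t) dt  (units: mm)
    t = np.linspace(-p, p, 4001)
    tri = p - np.abs(t)
    lags = np.arange(jmax + 1)
    gauss = (np.exp(-0.5 * ((lags[:, None] * p - t[None, :]) / s2) ** 2)
             / (s2 * math.sqrt(2.0 * math.pi)))
    k = np.trapezoid(tri[None, :] * gauss, t, axis=1)
    # T(f) = DTFT of the covariance sequence, normalized so T = 1 at no blur
    phases = np.cos(2.0 * np.pi * np.multiply.outer(f, lags) * p)
    return (k[0] + 2.0 * (phases[..., 1:] * k[1:]).sum(axis=-1)) / p


def theoretical_nnps_2d(cfg: ChainConfig, u: np.ndarray | float,
                        v: np.ndarray | float) -> np.ndarray:
    """Ground-truth 2-D NNPS (mm^2) of simulated flat fields at (u, v).

    Quantum term: ``gain^2 q p^4 T(u) T(v)`` with ``T`` the aliased squared
    blur/aperture transfer (separable for a Gaussian PSF and square
    aperture); electronic term: ``sigma_e^2 p^2``; both divided by the
    squared mean signal ``(gain q p^2)^2``.
    """
    mean = cfg.gain * cfg.mean_counts_per_pixel
    if mean == 0:
        raise NormalizationError("zero mean signal: NNPS normalization undefined")
    p = cfg.pixel_pitch
    tu = _aliased_quantum_transfer(np.asarray(u, float), cfg.blur_sigma, p)
    tv = _aliased_quantum_transfer(np.asarray(v, float), cfg.blur_sigma, p)
    quantum = cfg.gain**2 * cfg.fluence * p**4 * tu * tv
    electronic = cfg.electronic_sigma**2 * p**2
    return (quantum + electronic) / mean**2


def theoretical_nnps(cfg: ChainConfig, f: np.ndarray | float) -> np.ndarray:
    """Ground-truth axial 1-D NNPS (mm^2) at on-axis frequency ``f``."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or np.any(f > cfg.nyquist + 1e-9):
        raise ConfigError("f must lie in [0, Nyquist]")
    return theoretical_nnps_2d(cfg, f, 0.0)


def theoretical_nnps_axial(cfg: ChainConfig, f: np.ndarray | float,
                           roi_side: int, n_bins: int = 7) -> np.ndarray:
    """Ground truth matched to the axial 1-D reduction of the estimator.

    The axial reduction averages the ``n_bins`` off-axis rows/columns on each
    side of the frequency axes, where the 2-D spectrum is slightly lower than
    on-axis when blur is present; this helper averages the 2-D ground truth
    over exactly those (u, v) samples for a bias-free comparison.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    df = 1.0 / (roi_side * cfg.pixel_pitch)
    offsets = np.arange(1, n_bins + 1) * df
    out = np.empty_like(f)
    for i, fi in enumerate(f):
        out[i] = float(np.mean(theoretical_nnps_2d(cfg, fi, offsets)))
    return out


# ----------------------------------------------------------------------------
# illustrative detector presets
#
# The specification sheet does not quantify blur or electronic noise for the
# three detectors; these presets are ILLUSTRATIVE, chosen only to reproduce
# the qualitative resolution/noise trade-off of the scintillator-thickness
# series: blur sigma grows with thickness while the absorbed fraction of the
# incident quanta (quantum efficiency) grows with it too.

ILLUSTRATIVE_PRESETS: dict[str, dict[str, float]] = {
    "FXRD-4343VAW": dict(blur_sigma=0.050, quantum_efficiency=0.45,
                         electronic_sigma=1.0, gain=1.0),
    "FXRD-4343VAW Plus": dict(blur_sigma=0.075, quantum_efficiency=0.60,
                              electronic_sigma=1.0, gain=1.0),
    "FXRD-4343FAW": dict(blur_sigma=0.080, quantum_efficiency=0.75,
                         electronic_sigma=0.5, gain=1.0),
}


def illustrative_chain_config(detector: str, beam: str = "RQA5",
                              kerma: float = 2.5,
                              frame_shape: tuple[int, int] = (512, 512),
                              seed: int = 0) -> ChainConfig:
    """Illustrative simulator preset for a named detector.

    Fluence is the absorbed fluence ``eta * Ka * SNR^2/Ka`` at the given beam
    quality and air kerma; pitch comes from the specification sheet.  The
    blur/efficiency/electronic-noise numbers are illustrative (see module
    docstring), not measured values.
    """
    spec = get_detector_spec(detector)
    preset = ILLUSTRATIVE_PRESETS[spec.name]
    bq = get_beam_quality(beam)
    q = preset["quantum_efficiency"] * fluence_from_kerma(bq, kerma)
    return ChainConfig(
        fluence=q,
        pixel_pitch=spec.pixel_pitch_mm,
        blur_sigma=preset["blur_sigma"],
        gain=preset["gain"],
        electronic_sigma=preset["electronic_sigma"],
        frame_shape=frame_shape,
        seed=seed,
    )
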