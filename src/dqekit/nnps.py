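"""Normalized noise power spectrum estimation from flat-field series.

A homogeneous central region (1024 x 1024 pixels by default, or the largest
centered square the frames allow) is tiled with half-overlapping square ROIs
(side 128 or 256).  Each ROI is detrended by subtracting a least-squares 2-D
polynomial surface, its periodogram is computed, and the ensemble average is
scaled to physical units and normalized by the squared mean signal:

    NNPS(u, v) = pitch^2 / N^2 * < |FFT(I - S)|^2 > / S_bar^2     [mm^2]

where ``S`` is the per-ROI trend surface and ``S_bar`` the grand mean of the
flat-field signal.  The 1-D reduction averages either seven off-axis
rows/columns on each side of the frequency axes ("axial") or seven-bin-wide
annuli ("radial"); the zero-frequency bin is always excluded.
"""

from __future__ import annotations

import warnings

import numpy as np

from .curves import NNPS2D, NNPSCurve
from .exceptions import (ConfigError, InsufficientDataError,
                         NormalizationError)
from .frames import ImageFrame

__all__ = ["extract_rois", "detrend_roi", "nnps_2d", "nnps_1d", "measure_nnps"]


def _usable_side(frame_shape: tuple[int, int], region: int,
                 roi_side: int) -> int:
    """Largest tiling-compatible square side <= min(frame, region).

    Half-overlap tiling needs the side to be a multiple of ``roi_side / 2``.
    """
    half = roi_side // 2
    limit = min(frame_shape[0], frame_shape[1], region)
    return (limit // half) * half


def extract_rois(frames: list[ImageFrame], roi_side: int = 256,
                 region: int = 1024) -> list[np.ndarray]:
    """Tile the central region of every frame with half-overlapping ROIs.

    With a full ``region`` x ``region`` area the ROI count per frame is
    ``(2 * region / roi_side - 1)^2`` (49 for side 256, 225 for side 128 at
    region 1024).  Frames smaller than the region fall back to the largest
    centered square compatible with the tiling, with a warning.
    """
    if not frames:
        raise InsufficientDataError("no frames given")
    shape = frames[0].shape
    pitch = frames[0].pixel_pitch
    for fr in frames[1:]:
        if fr.shape != shape or fr.pixel_pitch != pitch:
            raise ConfigError("frames must share shape and pixel pitch")
    side = _usable_side(shape, region, roi_side)
    if side < roi_side:
        raise InsufficientDataError(
            f"frames of shape {shape} cannot host a single {roi_side}^2 ROI "
            f"within the {region}^2 analysis region")
    if side < region:
        warnings.warn(
            f"frames smaller than the {region}^2 analysis region; using the "
            f"largest centered square of side {side}", stacklevel=2)
    r0 = (shape[0] - side) // 2
    c0 = (shape[1] - side) // 2
    step = roi_side // 2
    starts = range(0, side - roi_side + 1, step)
    rois = []
    for fr in frames:
        central = fr.pixels[r0:r0 + side, c0:c0 + side]
        for ry in starts:
            for rx in starts:
                rois.append(central[ry:ry + roi_side, rx:rx + roi_side])
    return rois


def detrend_roi(roi: np.ndarray, order: int = 2) -> np.ndarray:
    """Subtract a least-squares 2-D polynomial surface of the given order.

    Order 0 is mean subtraction; order 1 a plane; order 2 the six-term
    quadratic surface.  The residual has zero mean to machine precision.
    """
    if order not in (0, 1, 2):
        raise ConfigError(f"detrend order must be 0, 1 or 2, got {order}")
    roi = np.asarray(roi, dtype=float)
    if order == 0:
        return roi - roi.mean()
    ny, nx = roi.shape
    # normalized coordinates for conditioning
    x = np.linspace(-1.0, 1.0, nx)
    y = np.linspace(-1.0, 1.0, ny)
    xx, yy = np.meshgrid(x, y)
    cols = [np.ones_like(xx), xx, yy]
    if order == 2:
        cols += [xx * yy, xx**2, yy**2]
    design = np.stack([c.ravel() for c in cols], axis=1)
    coef, *_ = np.linalg.lstsq(design, roi.ravel(), rcond=None)
    return roi - (design @ coef).reshape(roi.shape)


def nnps_2d(frames: list[ImageFrame], roi_side: int = 256,
            detrend_order: int = 2, region: int = 1024,
            reference: str = "surface") -> NNPS2D:
    """Ensemble-averaged 2-D NNPS of a flat-field series.

    Parameters
    ----------
    frames : list of ImageFrame
        At least two flat-field frames (ten is the usual protocol).
    roi_side : 128 or 256
        Side of the half-overlapping square ROIs.
    detrend_order : 0 | 1 | 2
        Order of the per-ROI trend surface subtracted before the transform.
    reference : "surface" or "mean_frame"
        "surface" (default) subtracts the per-ROI polynomial trend;
        "mean_frame" subtracts the pixelwise mean of the frame series first
        (removing fixed-pattern structure) and then the per-ROI mean.
    """
    if len(frames) < 2:
        raise InsufficientDataError("NNPS needs at least 2 flat-field frames")
    if reference not in ("surface", "mean_frame"):
        raise ConfigError(f"unknown reference mode {reference!r}")
    pitch = frames[0].pixel_pitch
    work = frames
    if reference == "mean_frame":
        mean_frame = np.mean([fr.pixels for fr in frames], axis=0)
        work = [ImageFrame(fr.pixels - mean_frame, pitch) for fr in frames]
    rois = extract_rois(work, roi_side=roi_side, region=region)
    # grand mean of the *signal* (always from the original frames)
    signal_rois = (rois if reference == "surface"
                   else extract_rois(frames, roi_side=roi_side, region=region))
    grand_mean = float(np.mean([r.mean() for r in signal_rois]))
    if grand_mean == 0:
        raise NormalizationError("zero mean signal: NNPS normalization undefined")
    order = detrend_order if reference == "surface" else 0
    accum = np.zeros((roi_side, roi_side))
    for roi in rois:
        resid = detrend_roi(roi, order)
        accum += np.abs(np.fft.fft2(resid)) ** 2
    n_rois = len(rois)
    nps = accum / n_rois * pitch**2 / roi_side**2
    values = np.fft.fftshift(nps) / grand_mean**2
    return NNPS2D(values=values, frequency_step=1.0 / (roi_side * pitch),
                  n_rois=n_rois)


def nnps_1d(spec2d: NNPS2D, mode: str = "axial",
            n_bins: int = 7) -> NNPSCurve:
    """Reduce a 2-D NNPS to a 1-D curve.

    ``axial``: for each on-axis frequency, average the ``n_bins`` (default
    seven) rows/columns on each side of both frequency axes, excluding the
    axes themselves.  ``radial``: average over ``n_bins``-wide annuli in
    radial frequency.  The zero-frequency bin is excluded in both modes.
    """
    side = spec2d.side
    c = side // 2  # DC index of the fftshifted grid
    vals = spec2d.values
    df = spec2d.frequency_step
    if mode == "axial":
        freqs, out = [], []
        offsets = np.r_[-np.arange(1, n_bins + 1), np.arange(1, n_bins + 1)]
        for j in range(1, side // 2 + 1):
            pos = c + j if c + j < side else c - j
            samples = np.concatenate([
                vals[c + offsets, pos],   # cut along u, off-axis in v
                vals[pos, c + offsets],   # cut along v, off-axis in u
            ])
            freqs.append(j * df)
            out.append(float(samples.mean()))
        return NNPSCurve(frequencies=np.array(freqs), values=np.array(out),
                         n_rois=spec2d.n_rois)
    if mode == "radial":
        u = (np.arange(side) - c)[None, :]
        v = (np.arange(side) - c)[:, None]
        radius = np.hypot(u, v)  # in bin units
        nyq_bins = side // 2
        freqs, out = [], []
        k = 0
        while k * n_bins < nyq_bins:
            lo, hi = k * n_bins, (k + 1) * n_bins
            ring = (radius >= lo) & (radius < hi) & (radius > 0)
            if np.any(ring):
                freqs.append((lo + hi) / 2.0 * df)
                out.append(float(vals[ring].mean()))
            k += 1
        return NNPSCurve(frequencies=np.array(freqs), values=np.array(out),
                         n_rois=spec2d.n_rois)
    raise ConfigError(f"unknown reduction mode {mode!r}")


def measure_nnps(frames: list[ImageFrame], roi_side: int = 256,
                 detrend_order: int = 2, region: int = 1024,
                 mode: str = "axial", reference: str = "surface") -> NNPSCurve:
    """End-to-end 1-D NNPS from a flat-field series."""
    spec = nnps_2d(frames, roi_side=roi_side, detrend_order=detrend_order,
                   region=region, reference=reference)
    return nnps_1d(spec, mode=mode)
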