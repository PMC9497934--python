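"""Phantom image-quality metrics: CNR and COV over rectangular ROIs.

    CNR = |S_A - S_B| / sqrt(sd_A^2 + sd_B^2)
    COV = sd / S

with ``S`` the ROI mean and ``sd`` the sample (n-1) standard deviation.
Both metrics are invariant under multiplication of the image by a positive
constant; CNR is additionally invariant under additive offsets, COV is not.
"""

from __future__ import annotations

import numpy as np

from .exceptions import NormalizationError
from .frames import ImageFrame, ROIRect, ROIStats

__all__ = ["roi_stats", "compute_cnr", "compute_cov"]


def roi_stats(image: ImageFrame, roi: ROIRect, ddof: int = 1) -> ROIStats:
    """Mean and standard deviation of the signal inside an ROI.

    ``ddof=1`` (default) gives the sample standard deviation; ``ddof=0``
    the population convention.
    """
    data = roi.extract(image)
    return ROIStats(mean=float(data.mean()),
                    sd=float(data.std(ddof=ddof)),
                    n=data.size)


def compute_cnr(image: ImageFrame, roi_a: ROIRect, roi_b: ROIRect,
                ddof: int = 1) -> float:
    """Contrast-to-noise ratio between a target and a background ROI."""
    a = roi_stats(image, roi_a, ddof=ddof)
    b = roi_stats(image, roi_b, ddof=ddof)
    denom = np.hypot(a.sd, b.sd)
    if denom == 0:
        raise NormalizationError("both ROI standard deviations are zero; "
                                 "CNR undefined")
    return abs(a.mean - b.mean) / denom


def compute_cov(image: ImageFrame, roi: ROIRect, ddof: int = 1) -> float:
    """Coefficient of variation (sd / mean) inside an ROI."""
    stats = roi_stats(image, roi, ddof=ddof)
    if stats.mean == 0:
        raise NormalizationError("ROI mean is zero; COV undefined")
    return stats.sd / stats.mean
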