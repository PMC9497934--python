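"""Sampled 1-D functions of spatial frequency (lp/mm).

MTF, NNPS and DQE results are all curves on an ascending frequency axis; the
specializations carry the metadata each metric needs (Nyquist frequency, ROI
count, kerma/beam).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, GeometryError


@dataclass
class FrequencyCurve:
    """A sampled function of spatial frequency.

    frequencies : lp/mm, strictly ascending.
    values : metric units (dimensionless for MTF/DQE, mm^2 for NNPS).
    """

    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frequencies.shape != self.values.shape or self.frequencies.ndim != 1:
            raise GeometryError("frequencies and values must be equal-length 1-D")
        if self.frequencies.size >= 2 and np.any(np.diff(self.frequencies) <= 0):
            raise GeometryError("frequencies must be strictly ascending")

    def __len__(self) -> int:
        return self.frequencies.size

    def interp(self, f: np.ndarray | float) -> np.ndarray:
        """Linear interpolation; extrapolation outside the support is refused."""
        f = np.asarray(f, dtype=float)
        lo, hi = self.frequencies[0], self.frequencies[-1]
        if np.any(f < lo - 1e-12) or np.any(f > hi + 1e-12):
            raise ConfigError(
                f"frequency outside curve support [{lo:g}, {hi:g}] lp/mm; "
                "extrapolation is not permitted"
            )
        return np.interp(f, self.frequencies, self.values)


@dataclass
class MTFCurve(FrequencyCurve):
    """Presampled modulation transfer function; values normalized to 1 at f=0."""

    nyquist: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.frequencies.size and abs(self.frequencies[0]) > 1e-12:
            raise GeometryError("MTF curve must start at f = 0")
        if not (self.nyquist > 0):
            raise ConfigError("nyquist must be > 0")


@dataclass
class NNPSCurve(FrequencyCurve):
    """1-D normalized noise power spectrum in mm^2."""

    n_rois: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise ConfigError("NNPS values must be >= 0")


@dataclass
class DQECurve(FrequencyCurve):
    """Detective quantum efficiency versus frequency at a stated exposure."""

    kerma: float = 0.0  # uGy
    beam: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise ConfigError("DQE values must be >= 0")


@dataclass
class NNPS2D:
    """2-D NNPS on a centered (u, v) grid (DC at the array center).

    values : mm^2, square grid with side equal to the ROI side.
    frequency_step : lp/mm per bin along each axis, ``1/(roi_side * pitch)``.
    n_rois : number of ROIs averaged.
    """

    values: np.ndarray
    frequency_step: float
    n_rois: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise GeometryError("NNPS2D values must be a square 2-D grid")
        if not (self.frequency_step > 0):
            raise ConfigError("frequency_step must be > 0")

    @property
    def side(self) -> int:
        return self.values.shape[0]

    @property
    def nyquist(self) -> float:
        return self.frequency_step * (self.side // 2)
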