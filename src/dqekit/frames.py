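"""Core containers: image frames and rectangular regions of interest.

An :class:`ImageFrame` is a 2-D array of linearized detector signal together
with the physical pixel pitch in millimetres.  The pitch is carried explicitly
because every frequency axis in the toolkit (MTF, NNPS, DQE) depends on it;
it is never inferred from file metadata.

ROI coordinates are 0-based with the origin at the top-left pixel, row-major:
``x`` indexes columns, ``y`` indexes rows, and extents are half-open
``[x, x + width) x [y, y + height)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError


@dataclass
class ImageFrame:
    """2-D grayscale radiographic frame with physical pixel pitch.

    Parameters
    ----------
    pixels : ndarray
        2-D array of linear detector signal (arbitrary output units).
    pixel_pitch : float
        Pixel pitch in mm (assumed square pixels).
    """

    pixels: np.ndarray
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise GeometryError(f"frame must be 2-D, got shape {self.pixels.shape}")
        if not (self.pixel_pitch > 0):
            raise GeometryError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency 1/(2*pitch) in lp/mm."""
        return 1.0 / (2.0 * self.pixel_pitch)


@dataclass(frozen=True)
class ROIRect:
    """Rectangle ``[x, x+width) x [y, y+height)`` in pixel coordinates."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise GeometryError(f"ROI extents must be positive, got {self}")
        if self.x < 0 or self.y < 0:
            raise GeometryError(f"ROI origin must be non-negative, got {self}")
        if self.width * self.height < 4:
            raise GeometryError(f"ROI area must be at least 4 pixels, got {self}")

    @property
    def area(self) -> int:
        return self.width * self.height

    def validate_within(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.x + self.width > cols or self.y + self.height > rows:
            raise GeometryError(
                f"ROI {self} exceeds frame of shape {rows}x{cols}"
            )

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices for indexing a frame array."""
        return (slice(self.y, self.y + self.height),
                slice(self.x, self.x + self.width))

    def extract(self, frame: ImageFrame | np.ndarray) -> np.ndarray:
        arr = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame)
        self.validate_within(arr.shape)
        return arr[self.slices()]

    def overlaps(self, other: "ROIRect") -> bool:
        return not (
            self.x + self.width <= other.x
            or other.x + other.width <= self.x
            or self.y + self.height <= other.y
            or other.y + other.height <= self.y
        )


@dataclass(frozen=True)
class ROIStats:
    """Mean, sample standard deviation (n-1) and pixel count of an ROI."""

    mean: float
    sd: float
    n: int
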