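"""Grayscale image containers with pixel-size metadata.

Bright-field micrographs are held as 2D float arrays.  The package follows
the dark-on-bright convention of bright-field imaging throughout: spheroid
cores and invading cells are *darker* than the surrounding matrix, so every
thresholding step downstream selects low-gray pixels as objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class GrayImage:
    """A 2D grayscale micrograph.

    Parameters
    ----------
    pixels : ndarray
        2D array of gray levels (any numeric dtype; converted to float64
        for computation).
    pixel_size : float, optional
        Physical pixel size in micrometres per pixel.  Required for any
        area measurement in square micrometres.
    """

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayImage requires a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("gray levels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("gray levels must be non-negative")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_tiff(cls, path, pixel_size: float | None = None) -> "GrayImage":
        arr = tifffile.imread(path)
        if arr.ndim == 3:  # collapse trivial channel axes
            arr = arr.squeeze()
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-plane grayscale TIFF")
        return cls(arr, pixel_size=pixel_size)

    def to_tiff(self, path, bit_depth: int = 8) -> None:
        """Write the image as an unsigned-integer TIFF (8 or 16 bit)."""
        if bit_depth == 8:
            out = np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)
        elif bit_depth == 16:
            out = np.clip(np.rint(self.pixels), 0, 65535).astype(np.uint16)
        else:
            raise ValueError("bit_depth must be 8 or 16")
        tifffile.imwrite(path, out)


@dataclass
class CorrectedImage:
    """A flat-field corrected image: unitless ratios around 1.0."""

    pixels: np.ndarray
    pixel_size: float | None = None
    source: GrayImage | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("corrected values must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]
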