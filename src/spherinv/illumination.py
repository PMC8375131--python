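"""Flat-field (illumination) correction.

Uneven bright-field illumination is removed by dividing the image by a
heavily Gaussian-blurred copy of itself (default sigma 40 px).  Slowly
varying background is levelled to ~1 while objects much smaller than the
blur scale keep their contrast as ratios below 1.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .images import CorrectedImage, GrayImage

DEFAULT_BG_SIGMA = 40.0

#: blurred values below this fraction of the image maximum are clamped
#: before division (numerical safety for pathological inputs)
DIVISION_FLOOR_FRACTION = 1e-6


def correct_illumination(
    img: GrayImage | np.ndarray,
    sigma: float = DEFAULT_BG_SIGMA,
    *,
    boundary_mode: str = "nearest",
) -> CorrectedImage:
    """Divide ``img`` by its Gaussian-blurred copy.

    Parameters
    ----------
    img : GrayImage or ndarray
        Input micrograph; an all-zero image is rejected (the ratio would
        be undefined everywhere).
    sigma : float
        Blur scale in pixels.  Structures much smaller than ``sigma``
        retain contrast; the illumination gradient is removed.
    boundary_mode : str
        Boundary handling for the blur.  The replicate-edge default
        avoids dark vignettes near borders that would masquerade as
        cells.

    Returns
    -------
    CorrectedImage
        Unitless ratio image; a perfectly flat input maps to 1
        everywhere, and the output is exactly invariant under positive
        rescaling of the input.
    """
    if not isinstance(img, GrayImage):
        img = GrayImage(img)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pixels = img.pixels
    peak = float(pixels.max())
    if peak <= 0:
        raise ValueError("all-zero image: illumination ratio undefined")

    blurred = ndi.gaussian_filter(pixels, sigma, mode=boundary_mode)
    floor = DIVISION_FLOOR_FRACTION * peak
    np.maximum(blurred, floor, out=blurred)
    return CorrectedImage(pixels / blurred, pixel_size=img.pixel_size,
                          source=img)
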