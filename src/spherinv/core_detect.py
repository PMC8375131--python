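"""Spheroid core detection and projected-area measurement.

The corrected image is blurred at about half the cell size to homogenise
the core, binarised with the histogram "Minimum" auto-threshold, and the
largest hole-filled connected component above a size cut is taken as the
core.  The same threshold-fill-largest route measures the whole-spheroid
projected area for the growth assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import (DegenerateHistogramError, EmptySegmentationError,
                     NoCoreFoundError)
from .illumination import correct_illumination
from .images import CorrectedImage, GrayImage

#: default cell size (diameter, px); the homogenising blur uses half of it
DEFAULT_CELL_SIZE = 24.0
DEFAULT_BLUR_SIGMA = DEFAULT_CELL_SIZE / 2.0

#: iteration cap for the Minimum method's histogram smoothing
MINIMUM_MAX_ITER = 10_000

N_HISTOGRAM_BINS = 256


def default_min_object_area(cell_size: float = DEFAULT_CELL_SIZE) -> float:
    """Size cut rejecting stray cell clumps as "core": pi*(2*cell_size)^2."""
    return float(np.pi * (2.0 * cell_size) ** 2)


@dataclass
class CoreDetection:
    """Detected spheroid core: centroid, mask and size."""

    center: tuple[float, float]  # (x, y) in pixels
    core_mask: np.ndarray        # bool, same shape as the image
    core_area: float             # um^2 (px^2 when pixel_size is 1)
    core_equiv_radius: float     # px, radius of the equal-area circle
    threshold: float             # gray level used for binarisation

    @property
    def pixel_count(self) -> int:
        return int(np.count_nonzero(self.core_mask))


def _local_maxima(hist: np.ndarray) -> list[int]:
    """Indices of local maxima, plateaus counted once (rise-then-fall scan)."""
    maxima: list[int] = []
    direction = 1
    for i in range(hist.size - 1):
        if direction > 0:
            if hist[i + 1] < hist[i]:
                direction = -1
                maxima.append(i)
        else:
            if hist[i + 1] > hist[i]:
                direction = 1
    return maxima


def threshold_minimum(
    histogram, max_num_iter: int = MINIMUM_MAX_ITER
) -> int:
    """Histogram "Minimum" auto-threshold.

    The histogram is repeatedly smoothed with a 3-bin moving mean until
    exactly two local maxima remain; the returned threshold is the bin of
    the minimum between them.  Smoothing stops as soon as bimodality
    holds (an already-bimodal histogram is not smoothed at all).

    Parameters
    ----------
    histogram : array-like of counts

    Returns
    -------
    int
        Threshold bin index.

    Raises
    ------
    DegenerateHistogramError
        If the histogram has fewer than two populated bins or never
        becomes bimodal within the iteration cap.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "histogram needs at least two populated bins"
        )
    smooth = hist.copy()
    for _ in range(max_num_iter + 1):
        maxima = _local_maxima(smooth)
        if len(maxima) == 2:
            lo, hi = maxima
            return lo + int(np.argmin(smooth[lo:hi + 1]))
        smooth = ndi.uniform_filter1d(smooth, size=3, mode="nearest")
    raise DegenerateHistogramError(
        f"histogram did not become bimodal within {max_num_iter} smoothing "
        "iterations"
    )


def _minimum_threshold_value(pixels: np.ndarray) -> float:
    """Minimum-method threshold as a gray value (256-bin quantisation)."""
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        raise DegenerateHistogramError("constant image")
    hist, edges = np.histogram(pixels, bins=N_HISTOGRAM_BINS, range=(lo, hi))
    t_bin = threshold_minimum(hist)
    return float((edges[t_bin] + edges[t_bin + 1]) / 2.0)


def _largest_filled_component(binary: np.ndarray, min_object_area: float):
    """Fill holes, label, drop small components, return the largest mask.

    Ties on size are broken by the lower label of the deterministic
    raster-order labelling.
    """
    filled = ndi.binary_fill_holes(binary)
    labels, n = ndi.label(filled)
    if n == 0:
        return None
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    counts[counts < min_object_area] = 0
    if counts.max() == 0:
        return None
    best = int(np.argmax(counts))  # argmax -> lowest label on ties
    return labels == best


def detect_core(
    img: CorrectedImage,
    blur_sigma: float = DEFAULT_BLUR_SIGMA,
    min_object_area: float | None = None,
) -> CoreDetection:
    """Locate the spheroid core in a corrected image.

    The image is blurred with ``blur_sigma`` (about half the cell size),
    binarised at the Minimum auto-threshold (dark side = object), holes
    are filled and components smaller than ``min_object_area`` (default
    ``pi*(2*cell_size)^2``) are discarded; the largest survivor is the
    core and its centroid the core center.
    """
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    if min_object_area is None:
        min_object_area = default_min_object_area()
    pixels = np.asarray(img.pixels, dtype=np.float64)
    smoothed = ndi.gaussian_filter(pixels, blur_sigma, mode="nearest")
    try:
        thr = _minimum_threshold_value(smoothed)
    except DegenerateHistogramError as exc:
        raise NoCoreFoundError(f"no core found: {exc}") from exc
    mask = _largest_filled_component(smoothed < thr, min_object_area)
    if mask is None:
        raise NoCoreFoundError(
            "no core found: no component above "
            f"{min_object_area:.0f} px^2 survived thresholding"
        )
    count = int(np.count_nonzero(mask))
    cy, cx = ndi.center_of_mass(mask)
    pixel_size = img.pixel_size if img.pixel_size is not None else 1.0
    return CoreDetection(
        center=(float(cx), float(cy)),
        core_mask=mask,
        core_area=count * pixel_size**2,
        core_equiv_radius=float(np.sqrt(count / np.pi)),
        threshold=thr,
    )


def measure_spheroid_area(
    img: GrayImage,
    manual_threshold: float | None = None,
    *,
    bg_sigma: float | None = None,
) -> float:
    """Projected spheroid area at its widest extension, in um^2.

    The image is flat-field corrected, thresholded (Minimum
    auto-threshold, or the caller-supplied ``manual_threshold`` on the
    corrected scale, standing in for a manual segmentation step), holes
    are filled and the largest component's pixel count is converted to
    um^2 via the pixel size.
    """
    if img.pixel_size is None:
        raise ValueError("pixel_size metadata is required for um^2 areas")
    from .illumination import DEFAULT_BG_SIGMA
    corrected = correct_illumination(
        img, DEFAULT_BG_SIGMA if bg_sigma is None else bg_sigma
    )
    if manual_threshold is None:
        thr = _minimum_threshold_value(corrected.pixels)
    else:
        thr = float(manual_threshold)
    mask = _largest_filled_component(corrected.pixels < thr,
                                     min_object_area=1)
    if mask is None:
        raise EmptySegmentationError(
            f"empty segmentation at threshold {thr:.4g}"
        )
    return float(np.count_nonzero(mask)) * img.pixel_size**2
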