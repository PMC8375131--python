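"""Invasion quantification from a corrected image and detected core.

Cells are segmented by Otsu's threshold, the invaded area is the cell
area outside the (dilated) core, and invasion distance is read off a
polar-transform radial profile: the fraction of angular samples that are
cell pixels, as a function of radius from the core center.  Two
characteristic radii are extracted from the profile:

* the core radius - the radius beyond which fewer than 50% of angular
  samples are cell pixels (and the profile never returns above 50%), and
* the maximum invasion radius ``r_max_invasion`` - the x-intercept of an
  ordinary least-squares line fitted to the declining tail of the curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .core_detect import CoreDetection
from .errors import ProfileError
from .images import CorrectedImage

logger = logging.getLogger(__name__)

CORE_YIELD_CRITERION = 0.5
DEFAULT_TAIL_LO = 0.02
DEFAULT_TAIL_HI = 0.20
#: minimum tail length for the OLS x-intercept to be trusted; an
#: extrapolation from fewer noisy points is numerically meaningless and
#: the documented last-nonzero-radius fallback is used instead
DEFAULT_MIN_TAIL_POINTS = 8
DEFAULT_N_ANGLES = 360
DEFAULT_R_LIMIT = 520  # px; half the default 1040-px image height


@dataclass
class RadialProfile:
    """Relative yield of cell pixels versus radius from the core center."""

    radii: np.ndarray            # 0 .. r_limit, unit step
    yield_: np.ndarray           # fraction of angular samples in [0, 1]
    r_limit: int
    center: tuple[float, float]  # (x, y)

    def __post_init__(self) -> None:
        if np.any(self.yield_ < 0) or np.any(self.yield_ > 1):
            raise ValueError("yield values must lie in [0, 1]")


@dataclass
class TailFit:
    """OLS line fitted to the declining tail of the radial profile."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    fallback: bool  # True when the documented last-nonzero fallback fired


@dataclass
class InvasionMetrics:
    """Per-spheroid invasion summary."""

    core_radius: float           # px
    r_max_invasion: float        # px
    tail_fit: TailFit
    invaded_area: float | None = None  # um^2, filled by the pipeline

    def __post_init__(self) -> None:
        if self.core_radius > self.r_max_invasion:
            raise ValueError("core_radius must not exceed r_max_invasion")


def segment_cells_otsu(img: CorrectedImage) -> np.ndarray:
    """Binary cell mask from Otsu's threshold on the corrected image.

    The threshold maximises the between-class variance of a 256-bin
    histogram spanning the corrected image's range; dark-side pixels
    (cells, in the bright-field convention) are flagged.
    """
    pixels = np.asarray(img.pixels, dtype=np.float64)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        raise ValueError("constant image: Otsu threshold undefined")
    hist, edges = np.histogram(pixels, bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    thr = threshold_otsu(hist=(hist, centers))
    # the cut bin belongs to the dark class, so classify against its
    # upper EDGE (the bin-center value would split the bin itself)
    idx = int(np.searchsorted(centers, thr))
    return pixels < edges[idx + 1]


def measure_invaded_area(
    mask: np.ndarray, core: CoreDetection, pixel_size: float
) -> float:
    """Cell area outside the core, in um^2.

    The detected core mask is dilated by 1 px before removal, so core
    boundary pixels are never counted as invading cells.
    """
    if mask.shape != core.core_mask.shape:
        raise ValueError("cell mask and core mask must share dimensions")
    core_dilated = ndi.binary_dilation(core.core_mask)
    count = int(np.count_nonzero(mask & ~core_dilated))
    return count * pixel_size**2


def polar_profile(
    mask: np.ndarray,
    center: tuple[float, float],
    r_limit: int = DEFAULT_R_LIMIT,
    n_angles: int = DEFAULT_N_ANGLES,
) -> RadialProfile:
    """Ray-based polar transform of a cell mask.

    For each radius ``r = 0 .. r_limit`` the mask is sampled
    (nearest-neighbour) at ``n_angles`` equally spaced angles around
    ``center``; the yield at ``r`` is the flagged fraction of those
    samples.  Per-radius denominators are constant, giving equal angular
    weighting of the cell distribution in all directions.  ``r_limit`` is
    capped at half the image height and at the distance from the center
    to the nearest border (clipped with a logged warning if exceeded).
    """
    h, w = mask.shape
    cx, cy = center
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError("center must lie inside the image")
    border_safe = int(np.floor(min(cx, cy, w - 1 - cx, h - 1 - cy)))
    cap = min(border_safe, h // 2)
    if r_limit > cap:
        logger.warning(
            "r_limit %d exceeds the border-safe radius %d; clipping",
            r_limit, cap,
        )
        r_limit = cap
    radii = np.arange(0, r_limit + 1)
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    xs = np.rint(cx + radii[:, None] * np.cos(theta)[None, :]).astype(int)
    ys = np.rint(cy + radii[:, None] * np.sin(theta)[None, :]).astype(int)
    samples = mask[ys, xs]
    return RadialProfile(
        radii=radii,
        yield_=samples.mean(axis=1).astype(np.float64),
        r_limit=int(r_limit),
        center=(float(cx), float(cy)),
    )


def _final_band_run(yield_, lo, hi, r_end):
    """Last maximal contiguous run of radii with lo <= yield <= hi."""
    in_band = (yield_ >= lo) & (yield_ <= hi)
    in_band[r_end + 1:] = False
    idx = np.flatnonzero(in_band)
    if idx.size == 0:
        return idx
    breaks = np.flatnonzero(np.diff(idx) > 1)
    start = idx[breaks[-1] + 1] if breaks.size else idx[0]
    return idx[idx >= start]


def extract_metrics(
    profile: RadialProfile,
    tail_lo: float = DEFAULT_TAIL_LO,
    tail_hi: float = DEFAULT_TAIL_HI,
    min_tail_points: int = DEFAULT_MIN_TAIL_POINTS,
) -> InvasionMetrics:
    """Core radius and maximum invasion radius from a radial profile.

    core radius
        The smallest radius from which the yield stays below 50%.
    r_max_invasion
        The tail of the profile - the final contiguous run of radii with
        yield between ``tail_lo`` and ``tail_hi`` times the profile
        maximum, preceding the last non-zero radius - is fitted by
        ordinary least squares and the line's x-intercept is returned,
        clipped to ``[core_radius, r_limit]``.  With fewer than
        ``min_tail_points`` tail points (never below 3), or a
        non-negative fitted slope, the documented fallback returns the
        last radius with non-zero yield and flags the fit.
    """
    if not 0 <= tail_lo < tail_hi:
        raise ValueError("need 0 <= tail_lo < tail_hi")
    y = np.asarray(profile.yield_, dtype=np.float64)
    r = np.asarray(profile.radii, dtype=np.float64)
    max_yield = float(y.max())
    if max_yield <= CORE_YIELD_CRITERION:
        raise ProfileError(
            f"profile max yield {max_yield:.3f} <= "
            f"{CORE_YIELD_CRITERION}: no core plateau present"
        )

    above = np.flatnonzero(y >= CORE_YIELD_CRITERION)
    last_above = int(above[-1])
    core_radius = float(r[last_above] + 1) if last_above + 1 < r.size \
        else float(r[-1])

    nonzero = np.flatnonzero(y > 0)
    r_end = int(nonzero[-1])
    tail_idx = _final_band_run(y, tail_lo * max_yield, tail_hi * max_yield,
                               r_end)

    fallback = tail_idx.size < max(3, min_tail_points)
    slope = intercept = rsq = np.nan
    r_max = float(r[r_end])
    if not fallback:
        rt, yt = r[tail_idx], y[tail_idx]
        slope, intercept = np.polyfit(rt, yt, 1)
        if slope >= 0:
            fallback = True
        else:
            pred = slope * rt + intercept
            ss_res = float(np.sum((yt - pred) ** 2))
            ss_tot = float(np.sum((yt - yt.mean()) ** 2))
            rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            r_max = -intercept / slope
    r_max = float(np.clip(r_max, core_radius, profile.r_limit))
    return InvasionMetrics(
        core_radius=min(core_radius, r_max),
        r_max_invasion=r_max,
        tail_fit=TailFit(
            slope=float(slope), intercept=float(intercept),
            r_squared=float(rsq), n_points=int(tail_idx.size),
            fallback=bool(fallback),
        ),
    )
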