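"""Synthetic spheroid micrographs and growth curves with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a compact dark spheroid core on a brighter background, carrying a
  granular internal texture (real bright-field cores are heavily textured;
  this texture is what keeps the core classifiable after flat-field
  division, whose sigma-40 blur flattens any structure much larger than
  the blur scale),
* small dark invading-cell blobs scattered radially around the core up to
  a known outermost centroid radius, one blob pinned exactly at that
  radius so maximum-radius recovery has an exact truth,
* a smooth multiplicative illumination field spanning a known max/min
  ratio across the frame, and
* additive Gaussian sensor noise clipped to the gray range.

Growth-curve simulation produces per-replicate exponential area series
with lognormal multiplicative noise and an optional post-plateau hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import SceneCapacityError
from .images import GrayImage

GRAY_MAX = 255.0  # 8-bit rendering range

#: total blob area may exceed the centroid annulus by at most this factor
#: (blob-blob overlap is allowed, so the limit only rejects absurd specs)
CAPACITY_FACTOR = 5.0


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic spheroid scene.

    Defaults give a 1040x1040 px frame (so the radial limit of half the
    image height is 520 px) with a 150 px core and 300 invading cells of
    6 px radius out to 410 px, a mild 1.5x illumination gradient and
    4 gray levels of sensor noise.
    """

    image_width: int = 1040
    image_height: int = 1040
    core_center: tuple[float, float] = (520.0, 520.0)  # (x, y)
    core_radius_true: float = 150.0
    n_invading_cells: int = 300
    cell_radius: float = 6.0
    r_outermost_true: float = 410.0
    radial_distribution: str = "triangular"  # "uniform" | "triangular"
    illumination_gradient_ratio: float = 1.5
    noise_sd: float = 4.0
    core_gray: float = 60.0
    cell_gray: float = 80.0
    background_gray: float = 200.0
    texture_coverage: float = 0.65  # granule area fraction inside the core
    texture_depth: float = 0.25    # granule gray = texture_depth * core_gray
    texture_scale: float = 2.5     # granule correlation length, px
    seed: int = 0

    def validate(self) -> None:
        w, h = self.image_width, self.image_height
        if w <= 0 or h <= 0:
            raise ValueError("image dimensions must be positive")
        if self.core_radius_true <= 0:
            raise ValueError("core_radius_true must be positive")
        if self.n_invading_cells < 0:
            raise ValueError("n_invading_cells must be >= 0")
        if self.radial_distribution not in ("uniform", "triangular"):
            raise ValueError(
                f"unknown radial_distribution {self.radial_distribution!r}"
            )
        if self.illumination_gradient_ratio < 1:
            raise ValueError("illumination_gradient_ratio must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (self.cell_gray < self.background_gray
                and self.core_gray < self.background_gray):
            raise ValueError("objects must be darker than the background")
        if self.n_invading_cells > 0:
            r_cap = min(w, h) / 2 - self.cell_radius
            if not (self.core_radius_true < self.r_outermost_true <= r_cap):
                raise ValueError(
                    "need core_radius_true < r_outermost_true <= "
                    "min(width, height)/2 - cell_radius"
                )
            inner = self.core_radius_true + self.cell_radius
            if self.r_outermost_true < inner:
                raise SceneCapacityError(
                    "annulus too thin: outermost radius "
                    f"{self.r_outermost_true} leaves no room for blobs of "
                    f"radius {self.cell_radius} clearing the core"
                )
            annulus = math.pi * (self.r_outermost_true**2 - inner**2)
            blob_area = self.n_invading_cells * math.pi * self.cell_radius**2
            if blob_area > CAPACITY_FACTOR * max(annulus, 1.0):
                raise SceneCapacityError(
                    f"{self.n_invading_cells} blobs of radius "
                    f"{self.cell_radius} px exceed {CAPACITY_FACTOR}x the "
                    f"annulus area ({annulus:.0f} px^2)"
                )


@dataclass(frozen=True)
class GrowthSpec:
    """Parameters of a simulated spheroid-area time series.

    ``k`` is the exponential growth rate in 1/day, ``Y0`` the projected
    area on day 0 in um^2 and ``cv_noise`` the coefficient of variation of
    the multiplicative (lognormal, mean-one) observation noise.
    """

    Y0: float = 1.2e5
    k: float = 0.188
    days: tuple = tuple(range(1, 11))
    cv_noise: float = 0.05
    plateau_day: float | None = None
    n_replicates: int = 24
    seed: int = 0

    def validate(self) -> None:
        if self.Y0 <= 0:
            raise ValueError("Y0 must be positive")
        days = np.asarray(self.days, dtype=float)
        if days.size == 0 or np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SyntheticTruth:
    """Generator-side ground truth for recovery tests."""

    seed: int
    core_radius_true: float | None = None
    r_outermost_true: float | None = None
    n_invading_cells: int | None = None
    invaded_area_true: float | None = None  # um^2 (pixel_size = 1 um/px)
    k_true: float | None = None
    Y0_true: float | None = None
    placements: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class GrowthSeries:
    """One spheroid's projected-area time series."""

    spheroid_id: str
    group: str
    days: np.ndarray
    areas: np.ndarray


def _sample_radii(rng, n, law, r_in, r_out, floor):
    """Sample centroid radii on (r_in, r_out], rejecting core overlap."""
    out = np.empty(n)
    got = 0
    while got < n:
        u = rng.uniform(size=n - got)
        if law == "uniform":
            r = r_in + u * (r_out - r_in)
        else:  # triangular-decaying: density proportional to (r_out - r)
            r = r_out - (r_out - r_in) * np.sqrt(u)
        r = r[r >= floor]
        out[got:got + r.size] = r
        got += r.size
    return out


def _paint_disk(labels, cx, cy, radius, value):
    """Set ``labels`` to ``value`` on the rasterized disk (d^2 <= r^2)."""
    h, w = labels.shape
    x0, x1 = int(max(0, np.floor(cx - radius))), int(min(w, np.ceil(cx + radius) + 1))
    y0, y1 = int(max(0, np.floor(cy - radius))), int(min(h, np.ceil(cy + radius) + 1))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    labels[y0:y1, x0:x1][inside] = value


def _core_texture(rng, shape, coverage, scale):
    """Binary granule field covering ``coverage`` of the area.

    A Gaussian random field smoothed at ``scale`` px is thresholded at the
    coverage quantile, giving granules with a controlled correlation
    length and an exact area fraction.
    """
    field_ = ndi.gaussian_filter(rng.standard_normal(shape), scale)
    thr = np.quantile(field_, coverage)
    return field_ <= thr


def _illumination_field(shape, ratio):
    """Smooth multiplicative field in [1/ratio, 1] along the diagonal."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    s = (xx + yy) / max(w + h - 2, 1)
    lo = 1.0 / ratio
    return lo + (1.0 - lo) * s


def render_spheroid_image(spec: SceneSpec) -> tuple[GrayImage, SyntheticTruth]:
    """Render one synthetic spheroid scene.

    Returns the 8-bit-range grayscale image and the ground truth,
    including the full blob placement log.  The same spec (same seed)
    always yields a bit-identical image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    cx, cy = spec.core_center

    # object label raster: 0 background, 1 core, 2 invading cell
    labels = np.zeros((h, w), dtype=np.uint8)
    _paint_disk(labels, cx, cy, spec.core_radius_true, 1)

    n = spec.n_invading_cells
    if n > 0:
        floor = spec.core_radius_true + spec.cell_radius
        radii = np.empty(n)
        radii[0] = spec.r_outermost_true  # pinned outermost blob
        if n > 1:
            radii[1:] = _sample_radii(
                rng, n - 1, spec.radial_distribution,
                spec.core_radius_true, spec.r_outermost_true, floor,
            )
        angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
        bx = cx + radii * np.cos(angles)
        by = cy + radii * np.sin(angles)
        for x, y in zip(bx, by):
            _paint_disk(labels, x, y, spec.cell_radius, 2)
        placements = pd.DataFrame(
            {"blob_id": np.arange(n), "x": bx, "y": by, "radius_from_center": radii}
        )
    else:
        placements = pd.DataFrame(
            columns=["blob_id", "x", "y", "radius_from_center"]
        )

    img = np.full((h, w), spec.background_gray, dtype=np.float64)
    core = labels == 1
    img[core] = spec.core_gray
    if core.any():
        granules = _core_texture(
            rng, (h, w), spec.texture_coverage, spec.texture_scale
        )
        img[core & granules] = spec.texture_depth * spec.core_gray
    img[labels == 2] = spec.cell_gray

    img *= _illumination_field((h, w), spec.illumination_gradient_ratio)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(h, w))
    np.clip(img, 0.0, GRAY_MAX, out=img)

    truth = SyntheticTruth(
        seed=spec.seed,
        core_radius_true=spec.core_radius_true,
        r_outermost_true=(spec.r_outermost_true if n > 0
                          else spec.core_radius_true),
        n_invading_cells=n,
        invaded_area_true=float(np.count_nonzero(labels == 2)),
        placements=placements,
    )
    return GrayImage(img, pixel_size=1.0), truth


def simulate_growth_series(
    spec: GrowthSpec, group: str = "sim", id_prefix: str = "sph",
) -> tuple[list[GrowthSeries], SyntheticTruth]:
    """Simulate replicate exponential growth series.

    Each replicate follows ``area(t) = Y0 * exp(k * t) * eps(t)`` with
    ``eps`` lognormal of coefficient of variation ``cv_noise`` and mean 1.
    If ``plateau_day`` is set, the realised area at the plateau day is
    held for every later day.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.days, dtype=float)
    sigma2 = math.log1p(spec.cv_noise**2)
    sigma = math.sqrt(sigma2)

    series = []
    for rep in range(spec.n_replicates):
        if sigma > 0:
            eps = rng.lognormal(-sigma2 / 2.0, sigma, size=days.size + 1)
        else:
            eps = np.ones(days.size + 1)
        areas = spec.Y0 * np.exp(spec.k * days) * eps[:-1]
        if spec.plateau_day is not None:
            plateau_value = (
                spec.Y0 * math.exp(spec.k * spec.plateau_day) * eps[-1]
            )
            late = days > spec.plateau_day
            # hold the realised plateau-day value afterwards; if the grid
            # contains the plateau day itself, hold that observation
            on_day = np.isclose(days, spec.plateau_day)
            if on_day.any():
                plateau_value = areas[on_day][0]
            areas[late] = plateau_value
        series.append(GrowthSeries(
            spheroid_id=f"{id_prefix}{rep:03d}", group=group,
            days=days.copy(), areas=areas,
        ))

    truth = SyntheticTruth(seed=spec.seed, k_true=spec.k, Y0_true=spec.Y0)
    return series, truth


def growth_series_frame(series: list[GrowthSeries]) -> pd.DataFrame:
    """Long-format table (spheroid_id, group, day, area_um2)."""
    rows = [
        {"spheroid_id": s.spheroid_id, "group": s.group,
         "day": d, "area_um2": a}
        for s in series for d, a in zip(s.days, s.areas)
    ]
    return pd.DataFrame(rows)


def scene_sweep(base: SceneSpec, seeds) -> list[SceneSpec]:
    """Convenience: the same scene re-rendered under different seeds."""
    return [replace(base, seed=int(s)) for s in seeds]
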