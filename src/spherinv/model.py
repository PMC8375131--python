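"""Model/Results surface for single-image invasion quantification.

`SpheroidInvasionModel` wraps the full per-image pipeline (flat-field
correction -> core detection -> Otsu cell segmentation -> polar radial
profile -> metric extraction) the way a statistical model wraps a fit:
the model holds the data and configuration, ``fit()`` returns an
:class:`InvasionResults` carrying every intermediate and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_detect import (DEFAULT_CELL_SIZE, CoreDetection,
                          default_min_object_area, detect_core)
from .illumination import DEFAULT_BG_SIGMA, correct_illumination
from .images import CorrectedImage, GrayImage
from .invasion import (DEFAULT_MIN_TAIL_POINTS, DEFAULT_N_ANGLES,
                       DEFAULT_R_LIMIT, DEFAULT_TAIL_HI, DEFAULT_TAIL_LO,
                       InvasionMetrics, RadialProfile, extract_metrics,
                       measure_invaded_area, polar_profile,
                       segment_cells_otsu)


@dataclass
class InvasionConfig:
    """Tunable parameters of the per-image pipeline.

    ``cell_size`` (px, diameter) drives both the core-homogenising blur
    (half the cell size) and the default minimum core area
    ``pi*(2*cell_size)^2``.
    """

    bg_sigma: float = DEFAULT_BG_SIGMA
    cell_size: float = DEFAULT_CELL_SIZE
    min_object_area: float | None = None
    r_limit: int = DEFAULT_R_LIMIT
    n_angles: int = DEFAULT_N_ANGLES
    tail_lo: float = DEFAULT_TAIL_LO
    tail_hi: float = DEFAULT_TAIL_HI
    min_tail_points: int = DEFAULT_MIN_TAIL_POINTS
    manual_cell_threshold: float | None = None

    @property
    def blur_sigma(self) -> float:
        return self.cell_size / 2.0

    def resolved_min_object_area(self) -> float:
        if self.min_object_area is not None:
            return self.min_object_area
        return default_min_object_area(self.cell_size)


@dataclass
class InvasionResults:
    """Fitted invasion quantification for one spheroid image."""

    image_id: str
    corrected: CorrectedImage = field(repr=False)
    core: CoreDetection = field(repr=False)
    cell_mask: np.ndarray = field(repr=False)
    profile: RadialProfile = field(repr=False)
    metrics: InvasionMetrics
    pixel_size: float
    config: InvasionConfig
    cell_threshold_used: str = "otsu"

    @property
    def core_radius(self) -> float:
        return self.metrics.core_radius

    @property
    def r_max_invasion(self) -> float:
        return self.metrics.r_max_invasion

    @property
    def invaded_area(self) -> float:
        return self.metrics.invaded_area

    def to_row(self) -> dict:
        """One flat record for the batch results CSV."""
        tf = self.metrics.tail_fit
        return {
            "image_id": self.image_id,
            "center_x": self.core.center[0],
            "center_y": self.core.center[1],
            "core_radius_px": self.metrics.core_radius,
            "core_equiv_radius_px": self.core.core_equiv_radius,
            "core_area_um2": self.core.core_area,
            "r_max_invasion_px": self.metrics.r_max_invasion,
            "invaded_area_um2": self.metrics.invaded_area,
            "tail_slope": tf.slope,
            "tail_intercept": tf.intercept,
            "tail_r_squared": tf.r_squared,
            "tail_n_points": tf.n_points,
            "tail_fallback": tf.fallback,
            "cell_threshold": self.cell_threshold_used,
        }

    def summary(self) -> str:
        tf = self.metrics.tail_fit
        tail = ("fallback: last non-zero radius" if tf.fallback else
                f"OLS on {tf.n_points} pts, R^2 = {tf.r_squared:.3f}")
        lines = [
            "Spheroid invasion quantification",
            "=" * 40,
            f"image:                {self.image_id}",
            f"core center (x, y):   ({self.core.center[0]:.1f}, "
            f"{self.core.center[1]:.1f}) px",
            f"core radius:          {self.metrics.core_radius:.1f} px "
            "(50% yield criterion)",
            f"r_max_invasion:       {self.metrics.r_max_invasion:.1f} px "
            f"({tail})",
            f"invaded area:         {self.metrics.invaded_area:.0f} um^2",
            f"core area:            {self.core.core_area:.0f} um^2",
        ]
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Radial yield curve with the core radius and tail fit marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.profile.radii, self.profile.yield_, lw=1,
                label="relative yield")
        ax.axvline(self.metrics.core_radius, ls="--", color="gray",
                   label="core radius")
        tf = self.metrics.tail_fit
        if not tf.fallback:
            rr = np.linspace(self.metrics.core_radius,
                             self.metrics.r_max_invasion, 50)
            ax.plot(rr, tf.slope * rr + tf.intercept, color="crimson",
                    label="tail fit")
        ax.axvline(self.metrics.r_max_invasion, ls=":", color="crimson",
                   label="r_max_invasion")
        ax.set_xlabel("radius r [px]")
        ax.set_ylabel("yield of cell pixels")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(loc="upper right", fontsize="small")
        return ax


class SpheroidInvasionModel:
    """Invasion quantification model for one bright-field micrograph."""

    def __init__(self, image: GrayImage | np.ndarray,
                 pixel_size: float | None = None,
                 config: InvasionConfig | None = None,
                 image_id: str = "image"):
        if not isinstance(image, GrayImage):
            image = GrayImage(image, pixel_size=pixel_size)
        elif pixel_size is not None:
            image.pixel_size = pixel_size
        if image.pixel_size is None:
            image.pixel_size = 1.0
        self.image = image
        self.config = config or InvasionConfig()
        self.image_id = image_id

    @classmethod
    def from_tiff(cls, path, pixel_size: float = 1.0,
                  config: InvasionConfig | None = None):
        img = GrayImage.from_tiff(path, pixel_size=pixel_size)
        return cls(img, config=config, image_id=str(path))

    def fit(self) -> InvasionResults:
        cfg = self.config
        corrected = correct_illumination(self.image, cfg.bg_sigma)
        core = detect_core(corrected, blur_sigma=cfg.blur_sigma,
                           min_object_area=cfg.resolved_min_object_area())
        if cfg.manual_cell_threshold is not None:
            cell_mask = corrected.pixels <= cfg.manual_cell_threshold
            used = f"manual:{cfg.manual_cell_threshold:g}"
        else:
            cell_mask = segment_cells_otsu(corrected)
            used = "otsu"
        profile = polar_profile(cell_mask, core.center,
                                r_limit=cfg.r_limit, n_angles=cfg.n_angles)
        metrics = extract_metrics(profile, tail_lo=cfg.tail_lo,
                                  tail_hi=cfg.tail_hi,
                                  min_tail_points=cfg.min_tail_points)
        metrics.invaded_area = measure_invaded_area(
            cell_mask, core, self.image.pixel_size
        )
        return InvasionResults(
            image_id=self.image_id, corrected=corrected, core=core,
            cell_mask=cell_mask, profile=profile, metrics=metrics,
            pixel_size=self.image.pixel_size, config=cfg,
            cell_threshold_used=used,
        )
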