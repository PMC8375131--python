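"""Batch orchestration for the two assay workflows.

`run_invasion_batch` chains correction, core detection, cell
segmentation, radial profiling and metric extraction over a directory of
TIFFs; `run_growth_batch` chains per-spheroid exponential fitting, group
summaries and group statistics over a long-format area CSV.  Both write
CSV outputs plus a machine-readable run manifest, and per-image failures
are logged and skipped rather than aborting the batch (excluded images
must be auditable, never silent).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import SchemaError, SpherinvError
from .growth import (ExponentialGrowthModel, fits_frame, summarize_growth,
                     GROWTH_CSV_COLUMNS)
from .model import InvasionConfig, SpheroidInvasionModel
from .stats import GroupSample, min_excludable_difference, t_test_unpaired

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Every tunable analysis constant, in one place.

    A config file (YAML key-value) mirrors these fields one-to-one; CLI
    flags override file values.
    """

    pixel_size: float = 1.0       # um/px
    bg_sigma: float = 40.0        # px, flat-field blur
    cell_size: float = 24.0       # px, cell diameter (blur = half of it)
    min_object_area: float | None = None  # px^2, default pi*(2*cell_size)^2
    r_limit: int = 520            # px, radial profile limit
    n_angles: int = 360
    tail_lo: float = 0.02
    tail_hi: float = 0.20
    min_tail_points: int = 8
    manual_cell_threshold: float | None = None
    fit_day_min: float = 1.0
    fit_day_max: float = 10.0
    alpha: float = 0.05
    t_test_variant: str = "pooled"
    control_group: str | None = None
    seed: int = 0
    output_dir: str = "spherinv_out"

    def __post_init__(self) -> None:
        if not (0 <= self.tail_lo < self.tail_hi < 0.5):
            raise ValueError("need 0 <= tail_lo < tail_hi < 0.5")
        for name in ("pixel_size", "bg_sigma", "cell_size", "r_limit",
                     "n_angles", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def invasion_config(self) -> InvasionConfig:
        return InvasionConfig(
            bg_sigma=self.bg_sigma, cell_size=self.cell_size,
            min_object_area=self.min_object_area, r_limit=self.r_limit,
            n_angles=self.n_angles, tail_lo=self.tail_lo,
            tail_hi=self.tail_hi, min_tail_points=self.min_tail_points,
            manual_cell_threshold=self.manual_cell_threshold,
        )


def write_manifest(out_dir: Path, config: RunConfig, extra: dict | None = None
                   ) -> Path:
    payload = {
        "package": "spherinv",
        "version": __version__,
        "numpy": np.__version__,
        "config": config.to_dict(),
    }
    if extra:
        payload.update(extra)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def run_invasion_batch(image_dir, config: RunConfig) -> pd.DataFrame:
    """Quantify every TIFF in ``image_dir``; one result row per image.

    Unreadable or unanalysable images are skipped with a logged error and
    recorded in ``skipped.csv``.  Outputs (results CSV, per-image profile
    CSVs, manifest) go to ``config.output_dir``.
    """
    image_dir = Path(image_dir)
    paths = sorted(p for p in image_dir.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff"))
    if not paths:
        raise FileNotFoundError(f"no TIFF images in {image_dir}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles_dir = out_dir / "profiles"
    profiles_dir.mkdir(exist_ok=True)

    rows, skipped = [], []
    for path in paths:
        try:
            model = SpheroidInvasionModel.from_tiff(
                path, pixel_size=config.pixel_size,
                config=config.invasion_config(),
            )
            model.image_id = path.name
            res = model.fit()
        except (SpherinvError, ValueError, OSError) as exc:
            logger.error("skipping %s: %s", path.name, exc)
            skipped.append({"image_id": path.name, "error": str(exc)})
            continue
        rows.append(res.to_row())
        pd.DataFrame({"r_px": res.profile.radii,
                      "yield": res.profile.yield_}).to_csv(
            profiles_dir / f"{path.stem}_profile.csv", index=False)

    results = pd.DataFrame(rows)
    results.to_csv(out_dir / "invasion_results.csv", index=False)
    pd.DataFrame(skipped, columns=["image_id", "error"]).to_csv(
        out_dir / "skipped.csv", index=False)
    write_manifest(out_dir, config,
                   {"n_images": len(paths), "n_ok": len(rows),
                    "n_skipped": len(skipped)})
    return results


def run_growth_batch(area_csv, config: RunConfig) -> dict:
    """Fit growth curves from a long-format CSV and compare groups.

    Emits per-spheroid fits, per-group summaries and (when at least two
    groups have n >= 2) pairwise t-tests with delta_min columns.
    Returns the three tables in a dict.
    """
    df = pd.read_csv(area_csv)
    missing = [c for c in GROWTH_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{area_csv}: missing columns {missing}")
    models = ExponentialGrowthModel.from_dataframe(df)
    fits = [m.fit(config.fit_day_min, config.fit_day_max) for m in models]
    fit_table = fits_frame(fits)
    summary = summarize_growth(fits)

    comparisons = []
    by_group = fit_table.groupby("group")["k"]
    groups = {g: v.to_numpy() for g, v in by_group}
    eligible = [g for g, v in groups.items() if v.size >= 2]
    if len(eligible) < 2:
        logger.info("fewer than two groups with n >= 2; comparisons skipped")
    else:
        control = config.control_group or sorted(eligible)[0]
        if control not in eligible:
            raise ValueError(f"control group {control!r} not eligible")
        ctrl = GroupSample(control, groups[control])
        for g in sorted(eligible):
            if g == control:
                continue
            other = GroupSample(g, groups[g])
            res = t_test_unpaired(ctrl, other,
                                  variant=config.t_test_variant,
                                  alpha=config.alpha)
            comparisons.append({
                "control": control, "group": g,
                "t_statistic": res.statistic, "p_value": res.p_value,
                "significant": res.significant, "stars": res.stars,
                "delta_min_pct_of_control": min_excludable_difference(
                    ctrl, other, alpha=config.alpha,
                    variant=config.t_test_variant),
            })
    comp_table = pd.DataFrame(
        comparisons,
        columns=["control", "group", "t_statistic", "p_value",
                 "significant", "stars", "delta_min_pct_of_control"])

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fit_table.to_csv(out_dir / "growth_fits.csv", index=False)
    summary.to_csv(out_dir / "growth_summary.csv", index=False)
    comp_table.to_csv(out_dir / "growth_comparisons.csv", index=False)
    write_manifest(out_dir, config, {"n_spheroids": len(fits)})
    return {"fits": fit_table, "summary": summary,
            "comparisons": comp_table}
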