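# spherinv

Quantification of spheroid invasion assays from bright-field microscopy.

Matrix-embedded tumour or fibroblast spheroids send out invading cells in
star-like patterns.  Two questions matter when comparing treatment groups
(for example irradiated versus mock-treated spheroids): *how many* cells
invade, and *how far* do they get?  `spherinv` answers both from plain
2D bright-field micrographs, and fits spheroid growth curves from
projected-area time series.  It is aimed at radiation-biology and
tumour-biology labs running ultra-low-attachment spheroid cultures, and
at anyone who wants a tested, scriptable replacement for ad-hoc
image-analysis macros.

## What it computes

**Invasion, per image.**  Starting from a grayscale micrograph *I*:

1. *Flat-field correction*: `C = I / G_sigma(I)` with a Gaussian blur of
   sigma = 40 px, levelling uneven illumination while objects smaller
   than the blur scale keep their contrast.
2. *Core detection*: blur `C` at about half the cell size, binarise with
   the histogram **Minimum** auto-threshold, fill holes and keep the
   largest component above a size cut; its centroid is the core centre.
3. *Cell segmentation*: **Otsu**'s threshold (maximum between-class
   variance on a 256-bin histogram) flags dark pixels as cells.
4. *Polar profiling*: for every radius r = 0..r_limit the cell mask is
   sampled at 360 equally spaced angles around the core centre; the
   yield y(r) is the flagged fraction.  Equal per-radius denominators
   weight all directions equally.
5. *Metrics*: the **core radius** is the radius from which y(r) stays
   below 50%; the **maximum invasion radius** r_max_invasion is the
   x-intercept of an ordinary least-squares line through the declining
   tail of y(r) (the final stretch with 2%-20% of the profile maximum);
   the **invaded area** is the cell area outside the (1-px-dilated)
   core, in um².

**Growth, per spheroid.**  Projected area follows
`Y(t) = Y0 * exp(k t)`; `k` (1/day) and `Y0` (um²) are estimated by OLS
on ln-area versus day over a configurable window (multiplicative noise
makes the log fit the natural choice; a nonlinear fit is available).

**Statistics.**  Two-way fixed-effects ANOVA with Tukey or Sidak
post-hoc comparisons, unpaired two-tailed Student t-tests (pooled or
Welch), and the minimum difference excludable at alpha = 0.05,
`delta_min = t_{1-alpha/2,df} * sqrt(s_a²/n_a + s_b²/n_b)`, reported as a
percentage of the control mean.

A synthetic-data module renders spheroid scenes (textured dark core,
invading-cell blobs with a known outermost radius, multiplicative
illumination gradient, sensor noise) and simulates growth series with
known rates, so every stage of the pipeline is testable against ground
truth.

## Worked example

```python
from spherinv import (SceneSpec, render_spheroid_image,
                      SpheroidInvasionModel, GrowthSpec,
                      simulate_growth_series, fit_exponential)

spec = SceneSpec(seed=7)          # 150 px core, 300 cells out to 410 px
img, truth = render_spheroid_image(spec)
res = SpheroidInvasionModel(img, image_id="demo").fit()
print(res.summary())
```

```
Spheroid invasion quantification
========================================
image:                demo
core center (x, y):   (520.6, 520.2) px
core radius:          150.0 px (50% yield criterion)
r_max_invasion:       415.0 px (fallback: last non-zero radius)
invaded area:         34147 um^2
core area:            67288 um^2
```

The detected centre is within a pixel of the true (520, 520), the core
radius matches the generated 150 px, and the maximum invasion radius of
415 px sits one cell radius beyond the outermost cell centroid placed at
410 px (this sparse tail used the documented last-non-zero-radius
fallback rather than the tail fit).  `res.plot_profile()` draws the
radial yield curve with both radii marked.

```python
series, _ = simulate_growth_series(GrowthSpec(k=0.188, seed=7), group="0Gy")
print(fit_exponential(series[0], 1, 10).summary())
```

```
Exponential growth fit (Y(t) = Y0 * exp(k t))
==============================================
spheroid:        sph000
group:           0Gy
method:          log-linear
fit window:      days 1-10  (n = 10)
k   [1/day]:     0.1878  (SE 0.0040, 95% CI 0.1786 to 0.1969)
Y0  [um^2]:      118791.9
R^2 (log):       0.9964
```

A single noisy replicate recovers the generating rate 0.188/day within
its standard error.

## Command line

```bash
spherinv simulate --what both --n-scenes 5 --out-dir scenes/
spherinv invade   --image-dir scenes/ --out-dir results/
spherinv growth   --areas-csv scenes/growth_series.csv --day-min 1 --day-max 10
spherinv stats    --csv measurements.csv --method sidak
```

All tabular outputs are CSV; every run writes a machine-readable
`run_manifest.json` with the full configuration.  Per-image failures in
a batch are logged to `skipped.csv`, never silently dropped.

## Layout

- `src/spherinv/synthetic.py` - scene and growth-curve generators with ground truth
- `src/spherinv/illumination.py` - flat-field correction
- `src/spherinv/core_detect.py` - Minimum auto-threshold, core detection, projected area
- `src/spherinv/invasion.py` - Otsu segmentation, polar profiling, invasion metrics
- `src/spherinv/growth.py` - `ExponentialGrowthModel` / `GrowthResults`, group summaries
- `src/spherinv/stats.py` - ANOVA post-hoc tests, t-tests, delta_min
- `src/spherinv/model.py` - `SpheroidInvasionModel` / `InvasionResults`
- `src/spherinv/pipeline.py`, `cli.py` - batch workflows and the `spherinv` CLI
- `docs/methods.md` - detailed methods note
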