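# Methods

This note documents the models and procedures implemented in `spherinv`,
the assumptions they make, the tunable parameters and their defaults,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Image pipeline

### Flat-field correction

Bright-field images carry a smooth multiplicative illumination field.
The corrected image is the ratio `C = I / G_sigma(I)` with a Gaussian
blur of `bg_sigma = 40 px`.  Any structure varying slowly relative to
the blur scale cancels to ~1; objects much smaller than `bg_sigma`
(single invading cells) keep their contrast as ratios below 1.  Two
consequences matter downstream:

* The *interior* of a large spheroid core also flattens to ~1 — only
  its internal texture and a dark band at the rim (about one blur scale
  wide) survive.  Core detection therefore relies on that rim band plus
  hole filling, exactly as it must on real, textured cores.
* A bright halo (> 1) appears in the background just outside the core,
  because the local blur average is depressed by the dark core.  It is
  harmless: all thresholds select the dark side.

Numerical choices: the blur uses replicate-edge padding (zero padding
would create dark vignettes that masquerade as cells near borders);
blurred values below `1e-6` of the image maximum are clamped before
division; everything is computed in float64 regardless of input bit
depth, with re-quantisation only on TIFF export.  The correction is
exactly invariant under positive rescaling of the input.

### Core detection

The corrected image is blurred with `sigma = cell_size / 2`
(`cell_size` default 24 px diameter) to homogenise the core, then
binarised with the histogram **Minimum** auto-threshold: the 256-bin
histogram is repeatedly smoothed with a 3-bin moving mean until exactly
two local maxima remain, and the threshold is the bin of the minimum
between them.  Smoothing stops as soon as bimodality holds, so an
already-bimodal histogram is not smoothed at all; a histogram that
never becomes bimodal within 10,000 iterations raises an error.  Dark
pixels are flagged, holes are filled (turning the rim band into a solid
disk), components smaller than `min_object_area` (default
`pi*(2*cell_size)²`, rejecting stray cell clumps) are discarded, and
the largest survivor is the core; ties break towards the lower label of
the deterministic raster-order labelling.  Its centroid is the core
centre used by the polar transform.

The projected spheroid area for growth assays uses the same
threshold-fill-largest route on the corrected image, with an optional
explicit threshold argument standing in for a manual segmentation step;
the threshold actually used is always recorded in the output.

### Cell segmentation

Otsu's threshold maximises the between-class variance of a 256-bin
histogram spanning the corrected image's range.  One binning subtlety:
the library routine returns the cut bin's *centre*, but Otsu's
partition assigns the whole cut bin to the dark class, so pixels are
classified against the cut bin's upper *edge*.  Without this, gray
values in the upper half of the cut bin (a rounding-scale sliver) would
flip class and exact noise-free recovery would fail.

### Polar profile and invasion metrics

The cell mask is sampled along rays: for each radius `r = 0..r_limit`
(unit step) and each of `n_angles = 360` equally spaced angles, the
nearest pixel to `centre + r(cos t, sin t)` is read; the yield `y(r)`
is the flagged fraction over angles.  Ray sampling (rather than an
image-warp polar resampling) keeps the per-radius denominator constant,
i.e. all directions are weighted equally.  `r_limit` defaults to 520 px
(half the default 1040-px image height) and is clipped, with a logged
warning, to the distance from the centre to the nearest border.

Two radii are extracted from `y(r)`:

* **Core radius** — the smallest radius from which the yield stays
  below 50% (operationally: one past the last radius with
  `y >= 0.5`).  The 50% rule assumes two populations contribute to the
  profile: core pixels (yield near 1) and invading cells (a minority of
  angular samples at every radius).  When the yield hovers *at* 50%
  near the rim the rule is discontinuous by construction — a
  one-sample change can move the crossing; the test suite therefore
  asserts robustness statements about medians over seeds, not about
  single knife-edge scenes.  How transient dips below 50% inside the
  core should be handled is genuinely ambiguous; the stay-below rule
  used here ignores them.
* **Maximum invasion radius** — the tail of the curve, defined as the
  final contiguous run of radii whose yield lies between `tail_lo` and
  `tail_hi` times the profile maximum (defaults 0.02 and 0.20),
  preceding the last non-zero radius, is fitted by OLS and the line's
  x-intercept is reported, clipped to `[core_radius, r_limit]`.
  Fallback: if the tail has fewer than `min_tail_points` points
  (default 8; 3 is the hard minimum) or the fitted slope is
  non-negative, the last radius with non-zero yield is reported instead
  and the result is flagged.  The default of 8 was set after observing
  that x-intercepts extrapolated from 3-6 noisy points of sparse
  profiles are numerically meaningless (they ranged over >100 px
  between near-identical renders of the same scene), while the
  fallback value is stable to 1-2 px.  All of `tail_lo`, `tail_hi`,
  `min_tail_points` are config-exposed.

The **invaded area** counts cell pixels outside the detected core mask
dilated by 1 px (so core boundary pixels are never counted as
invasion) and converts to um² via `pixel_size²`.  Under the
constant-cell-size assumption it is a proxy for the number of invading
cells.

## Growth model

`Y(t) = Y0 * exp(k t)` with `Y0` the projected area (um²) on day 0 and
`k` the growth rate (1/day).  The default estimator is OLS on
`ln(area)` versus day: the model is exactly linearisable and the
observation noise of areas spanning decades is multiplicative, so the
log fit is both exact on model-true data (k recovered to machine
precision) and approximately variance-stabilising on noisy data.  A
nonlinear least-squares fit on raw areas (initialised from the log fit)
is available via `method="nls"` for users who prefer additive-error
weighting; on clean data both agree.  Fit windows are configurable;
the shipped defaults mirror the two-cell-line convention of fitting
days 1-10 for fast-growing lines that plateau after day 10 and days
1-14 for slower lines.  Plateau behaviour is handled by window
restriction only — no Gompertz or logistic extension.

Group summaries report per-group mean and sample SD (n-1 denominator)
of `k` and `Y0`; single-fit groups report SD as NaN with `n = 1`.

## Statistics

* **Two-way ANOVA** (`value ~ A + B + A:B`, fixed effects, type-II sums
  of squares via statsmodels) with post-hoc comparisons between all
  design cells using the residual mean square: Tukey's studentized
  range (`q = |diff| / sqrt(MS_res/2 * (1/n_i + 1/n_j))`, p from the
  studentized-range distribution with k = number of cells) or Sidak
  (`p_adj = 1 - (1 - p)^m` over the m pairs).  Empty design cells are
  an error listing the missing cells.
* **Unpaired two-tailed t-test**, pooled by default (the classical
  Student test is valid under unequal sample sizes; Welch is available
  for unequal variances; both are recorded in output).  Degenerate
  zero-variance inputs follow fixed conventions: equal constant groups
  give p = 1, unequal constant groups give p = 0 with a note.
* **Minimum excludable difference**
  `delta_min = t_{1-alpha/2,df} * sqrt(s_a²/n_a + s_b²/n_b)` as a
  percentage of the control mean, with df from the chosen t variant.
  This is the critical mean difference that the two-sided test, given
  the observed variances and sample sizes, would just reject at alpha;
  a true difference of exactly delta_min is detected in ~50% of
  repeated experiments, which the suite verifies by simulation.
* Stars follow the strict convention `* p<0.05, ** p<0.01, *** p<0.001`
  on adjusted p-values.  No presentation rounding is applied — raw
  values are emitted and rounding is left to reporting layers.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
with every truth recorded (seed, core radius, outermost centroid
radius, cell count, drawn invaded area, placement log; growth rate and
initial area for curve simulation).  Defaults, chosen once to mimic a
2.5x bright-field setup with a 1040-px camera frame:

| parameter | default | rationale |
|---|---|---|
| frame | 1040 x 1040 px | half-height radial limit of 520 px |
| core radius | 150 px | typical embedded spheroid at this scale |
| invading cells | 300 blobs of radius 6 px | ~30 um cells; keeps their angular coverage a minority at every radius, as the 50% core rule requires |
| radial law | triangular-decaying on (core, r_out] | invader density declines with distance; a uniform law is available |
| pinned blob | 1 at exactly r_out | exact truth for maximum-radius recovery |
| core texture | granules covering 65% of the core at depth 0.25x core gray, ~2.5 px scale | real cores are granular; the texture is what keeps the core classifiable after flat-field division |
| gray levels | background 200, core 60, cells 80 (8-bit range) | dark-on-bright convention |
| illumination | multiplicative diagonal ramp in [1/ratio, 1], ratio 1.5 | spans the stated max/min ratio without clipping at the top of the gray range |
| noise | additive Gaussian, sd 4 gray levels | moderate sensor noise |

Blob placement rejects overlaps with the core (centroids start one cell
radius outside the rim) but allows blob-blob overlap, matching
chain-like invasion morphology; a capacity error rejects specs whose
total blob area exceeds 5x the annulus area (overlap means there is no
hard geometric limit; the cap only rejects absurd requests).  Identical
spec and seed give bit-identical output.

Growth series use lognormal multiplicative noise with mean 1 and the
requested coefficient of variation; with `plateau_day` set, the
realised value at the plateau day is held for all later days.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: elongated or irregular cell shapes and
fibroblast-led chains with orientation structure, out-of-focus light
and depth effects, spheroids near well walls, debris, vignetting beyond
a smooth monotone field, and any correlation between invasion and core
morphology.  Recovery results on synthetic scenes bound the pipeline's
algorithmic error, not its robustness to every real-world artefact.

## Problem sizes

The shipped test suite and the acceptance script use desk-scale
problem sizes chosen to exercise every code path in seconds: 24
replicate growth series per condition (matching 3-4 experiments of 8
replicates), 10-20 seeded 1040-px scenes per recovery claim, 10,000
repetitions for the t-test null-calibration check and 5,000 for the
delta_min power check.

## Known limitations

* The Minimum threshold's iterative smoothing is sensitive to histogram
  discretisation; the implementation checks bimodality *before* each
  smoothing pass (so it is idempotent on bimodal input), which can
  differ by a bin from library variants that smooth first.
* The 50% core criterion is discontinuous when near-rim yield sits at
  exactly 0.5 (see above).
* r_max_invasion is clipped at `r_limit`; invasion beyond half the
  frame is censored, as it must be for equal angular weighting.
* The pipeline is 2D: all metrics are projections; no account is taken
  of cells leaving the focal plane.
* Group comparisons assume independent spheroids; plate or experiment
  batch effects are not modelled (no mixed-effects support).
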