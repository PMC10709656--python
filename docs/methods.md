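# Methods

## Problem and scope

`contactguide` quantifies contact guidance: how fibroblast-like cells change
shape and migration when cultured on substrates patterned with parallel
ridges and grooves.  A condition is described by three dimensions — groove
width `G_w` and ridge width `R_w` (µm, 2–10), and groove depth `G_D` (nm,
330/725/1000) — plus a flat control with all dimensions zero.  The groove
long axis is +y throughout; x is the perpendicular.  The package measures
static morphology from traced cell outlines, dynamic migration statistics
from nucleus tracks sampled every 10 min, compares condition groups
nonparametrically, regresses population fractions on the topographic
dimensions, and evaluates the filopodia bending-angle model that
rationalizes the depth dependence.

Because raw recordings of this kind are rarely public, the package ships a
first-class synthetic-data generator that emulates the data structure the
analysis assumes, with known ground truth, so every estimator can be
validated by parameter recovery.

## Morphometry

A cell is a simple polygon (vertices in µm).  Area, centroid and second
central moments are computed by exact boundary integrals (Green's theorem),
not pixel counting.  The fitted ellipse matches the filled region's
covariance for orientation and aspect ratio and is then scaled so its area
equals the polygon area exactly — the behavior of the standard
image-analysis "fit ellipse" on filled shapes.  Boundary-vertex
least-squares fitting is deliberately not used: the measured object is the
filled region, not its trace.

* aspect ratio `alpha` = major/minor axis length (>= 1);
* alignment angle `theta` = acute angle between the major axis and the
  groove axis, folded into [0°, 90°];
* isotropic covariance (e.g. a square) is an orientation tie, resolved to
  0° deterministically;
* polygons with area below 1e-9 µm² or self-intersections are rejected with
  the offending cell id, never skipped silently.

Aspect ratios are normalized by the control cohort: `alpha_bar =
alpha / alpha_cont`, with `alpha_cont` the mean aspect ratio of included
control cells (median available as an option; the control pool is the whole
dataset's control set).  Population fractions use inclusive thresholds:
elongated means `alpha_bar >= 2`, aligned means `theta <= 2°`.  Alignment
histograms use 2° bins over [0°, 90°], half-open `[lo, hi)` with 90°
assigned to the last bin; fractions sum to 1 and the CDF ends at 1.

Exclusions: cells flagged as mitotic or as spreading over both flat and
patterned regions are removed before any statistic, and both reasons are
logged per cell.

## Migration statistics

Tracks are nucleus positions on a regular 10-min grid.  Inclusion requires
more than 6 h of track (> 360 min) and, on patterned substrates, the
nucleus staying on the pattern; the directional-orientation statistic
additionally requires at least 10 h (>= 600 min — inclusive, so a
600-min/61-sample track qualifies).  Both gates are configurable.

* **Directional orientation**: angle between the net start-to-end
  displacement and the groove axis, folded to [0°, 90°]; undefined (an
  error, not 0) for zero net displacement.
* **Angular displacement** `dtheta(t, delta)`: angle in [0°, 180°] between
  the displacement over `[t, t+delta]` and over `[t+delta, t+2*delta]`,
  for every grid start time (overlapping windows), evaluated at
  `delta` = 10/50/100/200 min and binned at 15°.  Pairs where either
  displacement is exactly zero are skipped and counted — the angle is
  genuinely undefined there, and imputing 0° would inflate the first bin.
* **Speeds**: `v_bar` = path length / elapsed time; decomposition
  `v_x = sum|dx|/T`, `v_y = sum|dy|/T`; the guidance ratio `v_y/v_x` is
  flagged infinite for purely axial motion.  Per step,
  `max(v_x, v_y) <= v_bar <= v_x + v_y` (triangle inequality).
* **Directional displacement ratio** `d_y(0, Delta)/D(0, Delta)`:
  signed groove-axis displacement `y(Delta) - y(0)` over the path length
  summed from the 10-min-sampled polyline.  `Delta` runs 10–600 min in
  10-min steps; off-grid values are rejected rather than resampled.  The
  classical directionality ratio `d/D` uses the straight-line distance in
  the numerator, so `|d_y/D| <= d/D <= 1` always.  Cohort curves report
  mean ± SEM per `Delta` (SEM with n−1; a single cell gives SEM 0,
  flagged n=1); both the signed mean and the mean of `|d_y|/D` are
  written, since back-and-forth movers cancel in the signed average while
  the absolute version measures guidance efficiency.
* **MSD / VACF**: MSD is time-averaged over overlapping windows per track,
  then ensemble-averaged.  The VACF at lag `tau` is the mean cosine
  similarity between step vectors separated by `tau`, pooled over tracks —
  1 at lag 0 by construction and independent of speed fluctuations, which
  makes it an unbiased probe of heading persistence.

## Group statistics

Kruskal–Wallis (tie-corrected, chi-square tail with k−1 df) is the omnibus
test; all-identical data are flagged degenerate with H = 0, p = 1 rather
than raising.  Post hoc, Dunn's z statistics on mean ranks (tie-corrected)
are adjusted by the Šidák rule `1 − (1 − p)^m` over all m = k(k−1)/2
pairs.  Box summaries use linearly interpolated quartiles (configurable
percentile method) with the 1.5·IQR fence rule; fence-crossers are listed
individually.

Population fractions are regressed on the topographic dimensions by
unweighted OLS with intercept: main effects `G_D` (nm), `R_w`, `G_w` (µm)
and all pairwise products; the three-way product is off by default
(switchable).  Control rows encode all predictors as 0, so the intercept
estimates the control fraction.  Case 1 restricts to depths 0–725 nm,
Case 2 to 0–1000 nm; comparing their R² quantifies the trend reversal
beyond 725 nm.  Constant responses are reported as R² = 0 with zero
slopes.  Rank-deficient designs (e.g. a single-depth grid, where `G_D` is
collinear with the pattern indicator) raise; the pipeline skips and logs
the regression in that case.

## Filopodia bending angle

`theta_f = arcsin(G_D / l_f)`, with `G_D` in nm and the filopodium length
`l_f` in µm (converted internally), output in degrees.  `G_D > l_f` is a
domain error reported with both values; tables flag undefined cells.  The
angle is 0 at zero depth, strictly increasing in depth, and invariant under
joint rescaling of depth and length.

## Synthetic cohort generator

Headings follow an AR(1) on the deviation `delta` from the nearer of the
two groove-axis directions: `delta' = rho*delta + s*eps` with
`rho = persistence` and stationary sd `1/(2*sqrt(axis_bias))`, the
small-angle match to an axial von Mises with concentration `axis_bias` on
the doubled angle.  At `axis_bias = 0` this reduces to a wrapped-normal
heading random walk with `E[cos(increment)] = persistence`, so the lag-one
VACF recovers the persistence parameter exactly in the isotropic regime.
`persistence = 0` draws independent headings (exact doubled-angle von
Mises sampling).  Both axis directions are equally likely and noise can
carry a heading across ±90°, producing the back-and-forth motion
characteristic of grooved substrates.  Step lengths are gamma-distributed
(CV 1/4) around a per-cell mean speed drawn with mean
`base_speed_um_per_min` and sd `speed_sd`, so cohort mean path speed is
calibrated to the base speed.

Outlines are discretized ellipses (64 vertices) with multiplicative radial
noise (sd 0.03; star-shaped, so noise cannot self-intersect), axial
(period-π) orientation about the groove axis, gamma-distributed aspect
ratios above 1, and gamma-distributed areas.

Defaults emulate the study conditions: 10-min sampling, 600-min tracks,
30 cells per condition, speeds 0.25–0.39 µm/min, mean areas
2100–2800 µm².  `study_params` maps groove depth to generator parameters
following the reported trends — guidance (heading bias, orientation
concentration, mean aspect) strengthens from 330 to 725 nm and saturates
or weakly reverses at 1000 nm; speed dips at 725 nm — and damps guidance
mildly for wider ridges/grooves (depth is the dominant modeled effect; no
mechanistic depth-to-bias law is claimed).  Aspect-ratio spread
(sd 3.0) reflects the broad elongation distributions of fibroblast
cohorts.

What the generator does *not* emulate: groove-wall collision mechanics,
cell–cell interactions, shape–motility coupling, heteroscedastic tracking
noise, or images of any kind.  Passing recovery tests therefore shows the
estimators are correct and well-calibrated on data with the assumed
statistical structure, not that real cells follow this walk model.

## Numerical choices

* Angles serialized in degrees, positions in µm, times in minutes.
* Histogram top edges (90°, 180°) land in the last bin.
* `arccos` arguments are clipped to [−1, 1]; displacement and
  directionality ratios are clipped at their mathematical bounds to absorb
  last-ulp rounding.
* Axis unit vectors snap components below 1e-12 to zero so purely axial
  motion decomposes exactly.
* CSV floats are written at fixed 6-decimal precision, which together with
  seeded generators makes re-runs byte-identical.
* Seeds: every cohort derives from a single integer seed; per-condition
  seeds are consecutive offsets kept below 2^31.

## Problem sizes

The shipped pipeline defaults analyze the full study layout (control plus
the three lateral series at three depths, 46 unique conditions, 30 cells
each at 61 samples per track) in a few seconds on one core.  Statistical
calibration tests use 2000 null replicates (Kruskal–Wallis type-I error)
and cohorts of 300–2000 cells for Monte-Carlo nulls; these sizes give
sampling errors comfortably below the asserted tolerances.

## Known limitations

* The ridge/groove-width dependence in the generator is a mild
  monotone damping, not a fitted law; regressions on synthetic data
  recover depth effects far more strongly than width effects.
* The Dunn–Šidák adjustment is the only multiple-comparison procedure
  offered; no mixed-effects or per-chip nesting.
* Outline ingestion is CSV only (polygon vertex lists); binary ImageJ ROI
  files are not parsed.
* The axial-concentration parameterization of the walk uses a small-angle
  Gaussian match to the von Mises stationary law; at weak bias
  (`axis_bias` ~ 0.5) the realized concentration deviates from the nominal
  value by a few percent.
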