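# Methods

This note documents the models, defaults and numerical choices behind
`epiqc`'s quality-control computations, what the synthetic phantoms do
and do not emulate, and the known limitations.

## Motion magnitude and censoring

The per-volume motion scalar is the Euclidean norm of the forward
differences of the six rigid-body parameters (three rotations in
degrees, three translations in mm), combined unweighted:
`enorm[t] = sqrt(Σᵢ (pᵢ[t] − pᵢ[t−1])²)`.  The first volume of every run
is defined to have enorm 0 — runs are acquired separately, so a
cross-run difference is meaningless.  Because rotations are in degrees
and translations in mm, one unit of enorm loosely corresponds to ~1 mm
or ~1° of inter-volume movement.

The per-volume **outlier fraction** is the share of in-mask voxels whose
value at that time is a temporal outlier of its own series.  The
detector removes a per-run linear trend (the cheapest model that keeps
slow drift from inflating the spread estimate), then thresholds
`|residual| > k · 1.4826 · MAD(residual)` with `k` the upper-tail
standard-normal quantile at `alpha/2` (default `alpha = 0.01`,
k ≈ 2.576).  1.4826 is the usual MAD→sd consistency factor.  Voxels
whose MAD is at numerical-noise scale (≤ 1e−12 relative to the series
magnitude) are declared outlier-free, so exactly constant series do not
trip on rounding error.  The quantity is named in the QC literature
without a prescribed estimator; this MAD-based rule is our
concretization and every parameter of it is exposed.

Censoring marks volume t when `enorm[t] > 0.3` (mm-deg) or
`outlier_fraction[t] > 0.1`; both limits are configurable and the
defaults follow widespread practice for task FMRI at ~3 mm voxels.
With `censor_prev` (default on), the volume *before* an
enorm-triggered one is also censored, since the movement happened
between the two volumes.  The neighbor rule deliberately applies only
to enorm triggers: an isolated intensity outlier says nothing about the
preceding volume.  Summaries report before-censoring (BC) and
after-censoring (AC) five-number statistics; AC is flagged empty rather
than invented when everything is censored.

Reporting mirrors the conventions of the standard single-subject review
file: "censor fraction" is rounded to 6 decimals, "fraction censored
per run" to 7, per-stimulus censored fractions to 3.

## Quality maps

**TSNR** is `mean(signal series) / sd(noise series)` per voxel, with
`sd` the ddof = 1 sample estimate.  Two stage presets fix what counts as
noise: after volume registration, noise is the residual of a per-run
Legendre polynomial detrend (order 2 by default); after regression,
noise is the supplied residual (errts) series.  Zero-variance voxels
get TSNR 0 and are counted, not dropped silently.

**GCOR** is the mean of the full V×V temporal correlation matrix over
the mask, *including* the diagonal, which makes it exactly the squared
norm of the mean unit-normalized series — an O(VT) identity used by the
implementation and checked against the O(V²T) brute force in tests.
The self-correlation terms add 1/V, negligible for realistic masks, and
keep the value in [0, 1].

**Radial correlation** correlates each voxel with a Gaussian-weighted
average of its neighborhood (FWHM 20 mm by default, sigma = FWHM/2.3548
per axis converted to voxel units).  Weights are truncated at 3 sigma,
normalized over in-mask voxels only (self included), and evaluated
separably as `smooth(data·mask)/smooth(mask)`; the tests compare this
against a dense direct-summation oracle with the identical truncated
kernel.  As FWHM grows the neighborhood average tends to the global
mask average and the map approaches corr_brain.

**corr_brain** correlates each voxel's residual series with the
brain-average residual; its display convention is a transparent
threshold at |r| = 0.3 with colorbar bounds at |r| = 0.6.

**Grayplot.**  Each in-mask series is detrended (per-run Legendre order
2) and then Z-scored — detrending first, so drift does not dominate the
variance normalization; the alternative order is defensible but less
comparable across subjects.  Values are clipped at the two-sided normal
tail for p = 0.001 (≈ 3.2905) so grayscale ranges are subject-
comparable.  "Similarity" ordering sorts rows by decreasing |r| with
the first principal component of the standardized data (computed by
SVD; PC1's sign fixed so it correlates nonnegatively with the mean
series; ties broken by voxel index).  The named ordering in the field
is not algorithmically specified; PC1-similarity is our reproducible
concretization.

## Degrees-of-freedom ledger and regression checks

Every censored time point, every regressor and every frequency bin
removed by band-passing costs one DF of the `n_total` available.
Band-pass cost is counted on the DFT grid: bins `k/(n·tr)` for
`k = 0..⌊n/2⌋`, each interior bin worth 2 DFs (sine and cosine), the DC
and (even n) Nyquist bins worth 1; bins outside `[f_low, f_high]` are
charged.  The discrete count converges to the continuum fraction
`1 − (f_high − f_low)/f_nyq` as n grows — for the classic 0.01–0.1 Hz
band that is 64% of DFs at TR = 2 s and 82% at TR = 1 s.  The ledger's
`df_used` field counts censoring plus regressors; the emitted review
label "degrees of freedom used" counts regressors only, matching the
printed review-file convention.  A negative remainder is flagged severe
rather than raised, because a report must still be produced.

Collinearity warnings use pairwise |Pearson r| between mean-removed
design columns, graded mild/medium/severe at 0.4/0.6/0.8 — thresholds
chosen as configurable defaults for the graded semantics, not taken
from any reference — plus the condition number of the column-normalized
matrix, severe when numerically rank-deficient.  Correlations are
computed over kept (uncensored) time points only, since that is the
data the regression actually sees.

Pre-steady-state detection flags leading volumes of each run whose
mask-mean intensity strictly exceeds (1 + 0.02) times the run's median
mask-mean, scanning to the first steady volume, at most 4.  The 2%
default separates the several-percent elevation typical of
non-equilibrium magnetization from drift-scale variation; the rule is
an original concretization of a named check.

## Artifact detectors

**Left-right flip.**  The local Pearson correlation (LPC) cost
partitions the mask into non-overlapping 5³-voxel blocks (≥ 8 in-mask
voxels each), computes the signed Pearson r within each block between
EPI and anatomical, and averages with block-size weights, negated so
lower is better.  The cost is compared for the anatomical as-is vs
mirrored across the left-right axis named by the orientation code;
a margin below `tie_tol = 1e−6` is reported as ambiguous instead of
guessed.  Unlike the full-pipeline version of this check, no
re-registration is performed per candidate — inputs must already share
a grid.  That keeps the check deterministic and desk-scale, at the cost
of requiring pre-aligned inputs; it is the one deliberate scope cut in
this module.

**Variance lines.**  Per voxel, the temporal sd of the detrended,
mean-scaled series; per in-plane (i, j) column, the 90th percentile of
sd along the slice axis (the third voxel axis by convention).  The 90th
percentile rather than the mean lets short bright segments register.
Candidate columns have score ≥ 3.0 times the median score of their
11×11 in-plane neighborhood — median normalization suppresses global
noise-level differences.  Adjacent candidates are merged
(8-connectivity), reporting each component's peak with voxel and world
coordinates.  An optional keep-vector restricts the variance estimate
to uncensored volumes, since motion spikes otherwise masquerade as
high-variance columns.  All parameters (detrend order 2, neighborhood
11, percentile 90, ratio 3.0) are exposed; the artifact is named in
the literature but the detector is ours.

**Intensity range.**  Min/max are taken from the *stored* (unscaled)
data so the 12-bit saturation check (max exactly 4095) and the
negative-value check see acquisition units even when NIfTI scale
factors are set.

**ROI tables.**  Depth is the iteration at which repeated face-adjacent
(6-neighbor) erosion removes a voxel, with out-of-grid treated as
background; the region's "central coordinate" is a maximum-depth voxel,
ties broken by smallest (i, j, k).  TSNR quartiles (linear
interpolation) are over nonzero-TSNR voxels only; zeros count toward
Nzer — the statistic volume, not the underlying EPI, defines "zero".
Warning thresholds (Nzer/Nvox ≥ 0.05/0.25/0.75; Dvox ≤ 3/2/1; T75 and
interquartile-slope cutoffs) are config defaults implementing graded
semantics whose directions, not values, come from QC practice; absolute
TSNR cutoffs in particular are acquisition-dependent and should be
tuned per study.

Warning levels form the total order none < undecided < mild < medium <
severe, and a block displays the maximum over its checks.  The mapping
from each detector outcome to a level (flip DO_FLIP → severe, any
variance line → medium, ...) is a table in `artifact_checks`.

## Report, ratings, display math

The report directory is self-contained (HTML + images + JSON, no
network resources) and built without timestamps by default, so a
rebuild from identical inputs is byte-identical — useful both for
caching and for verifying reproducibility.  Overlay display ranges use
the 90th (threshold) and 99th (max) percentiles of in-mask |values|;
sub-threshold voxels are drawn with opacity `(|v|/thr)²` and
suprathreshold regions outlined, so thresholding highlights rather than
hides.  Statistical thresholds use the two-sided t tail at p = 0.001.
Montage slices are chosen evenly within a light automask (voxels above
10% of peak intensity) so views are not wasted on empty field of view.

Ratings are "+" (good), "x" (bad), "?" (other) with free-text comments
per block plus an overall FINAL; saving a comment on an unrated block
auto-applies "?", and the invariant "comment ⇒ rated" holds after any
action sequence (property-tested).  The click-cycle order is +, x, ?,
back to +.  "×" is normalized to "x" on load.  Ratings persist only in
a JSON file in the QC directory; no live server is involved.

## Group tools

Filters on group tables use ANY-element semantics for vector cells (one
bad per-stimulus fraction should flag the subject) — a compatibility
assumption, as the reference behavior for multi-value fields is not
documented.  Missing cells never satisfy EQ or ordered comparisons but
do count as "varying"; missing data should surface, not hide.  Numeric
equality for EQ uses exact match for integers and 1e−9 relative
tolerance for floats.  The `gtkyd` scan records matrix dims, voxel
sizes, TR, time points, datum type, orientation, stored min/max,
slice-timing presence and the saturation flag, then runs VARY on every
property.

## The phantom generator

Phantoms default to 24×24×16 voxels at 3 mm isotropic, TR 2 s, 200
volumes — large enough for the radial-correlation and line detectors to
have meaningful neighborhoods, small enough that a 20-phantom battery
runs in seconds.  Baseline 1000 with noise sd 10 gives a volreg-stage
TSNR of ~100, typical of 3 T EPI; a mild quadratic drift (1% of
baseline) models scanner drift.  An ellipsoidal "brain" with a smooth
interior gradient and a dim blob on the +x side makes left and right
distinguishable, which the flip check needs.

Artifact realizations:

* **Motion spikes** are single-volume parameter steps; the affected
  volume is also shifted by an integer voxel count in-plane.  Integer
  shifts avoid interpolation, so the censoring truth derived from the
  parameter table agrees exactly with the image effect.
* **Variance lines** add noise of sd `gain × noise_sd` along a whole
  (i, j) column.
* **Bad coil** adds one latent series to one octant; **global signal**
  adds a latent to the whole mask, giving a shared-variance fraction
  g²/(g² + σ²) with the closed-form GCOR expectation used in tests.
* **Task** adds a boxcar percent-signal change in a planted region and
  emits the matching ideal regressor (plain boxcar; hemodynamic
  convolution is out of scope — ideal regressors are inputs).
* **Pre-steady** volumes are scaled by (1 + excess); **lr_flip**
  mirrors the EPI only, never the anatomical.

What the phantom does **not** emulate: physiological noise spectra,
spatial autocorrelation of thermal noise, EPI distortion and dropout,
ghosting, slice-timing structure, realistic hemodynamics, or
interpolation effects of real volume registration.  Detector tests
passing on phantoms therefore demonstrate correctness of the
implementations against their definitions and recoverability of
cleanly-injected artifacts — not field performance on real data, where
confound structure is richer.

Determinism: identical spec + seed produce byte-identical bundles
(written as uncompressed `.nii` so no compression metadata can leak
in).

## Problem sizes and tolerances

The test suite runs detector-recovery batteries at 20 seeds on the
default phantom and oracle equivalences on grids up to 16³ (dense
radial-correlation summation is O(V·K·T) and deliberately kept small);
analytic identities are asserted to 1e−10, separable-vs-dense smoothing
to 1e−6, and stochastic recoveries at the rates stated in the tests.
`scripts/acceptance.py` reruns the same batteries from scratch in
under a minute.

## Known limitations

* No registration anywhere: all paired volumes must share a grid, and
  the flip check's accuracy degrades with genuine misalignment.
* The outlier, pre-steady, variance-line and ROI-warning rules are
  original concretizations of named checks; their defaults are sensible
  but not canonical, and are all exposed for calibration.
* GCOR and corr_brain are computed on whatever series is supplied; on
  undetrended data the drift contributes shared variance (visible in
  the README example).
* The HTML report is static; interactive viewers and live rating
  servers are out of scope.
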