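# Methods

## Model and assumptions

All three tests treat a longitudinal dataset as a collection of noisy
curves: subject `s` contributes observations `(x_sj, y_sj)` at
uncoordinated positions along a continuous axis (time, age, dose, …).
No parametric shape is assumed; trajectories are summarized by loess —
locally estimated scatterplot smoothing — which fits a weighted
polynomial in a moving neighborhood and therefore follows arbitrary
smooth curves. Inference is by permutation: the null distribution of
each statistic is built by resampling the observed data under the
relevant exchangeability assumption, so it automatically reflects the
noise level, sampling density and distributional quirks of the dataset
at hand. The tests assume:

* exchangeability of subject labels between groups under the two-group
  null (subjects are independent; no confounding covariate drives group
  membership);
* exchangeability of each subject's responses across its own time
  points under the trend null (no autocorrelation beyond the trend
  itself);
* enough pooled data that a loess fit is meaningful (the `cut_sparse`
  guard, and at least `degree + 2` distinct x values).

Least-squares loess is sensitive to outliers; no robustness iterations
are performed (a documented limitation, not an option).

## The loess primitive

At query point `q`, the engine selects the `k = ceil(span * n)` nearest
training points (clamped to `[degree + 2, n]` so every local system is
solvable), weights them with the tricube kernel
`w = (1 - (d / d_max)^3)^3` where `d_max` is the largest selected
distance, and fits a weighted least-squares polynomial of the model
degree centered at `q`; the prediction is the polynomial's value at
`q`. Implementation notes:

* Points tied with the cutoff distance receive weight exactly zero, so
  weighting *all* points with the clipped kernel is identical to
  "select k nearest, taking all ties at the cutoff".
* If every selected distance is zero (replicated x stacked at the
  query) the prediction is the plain mean of the stacked responses; if
  all selected points are tied exactly at the cutoff (all weights
  vanish) the plain mean of the selected points is used.
* Local coordinates are scaled by the bandwidth and each local system
  is solved by QR of the sqrt-weighted design, keeping predictions
  accurate to ~1e-12 against a brute-force reference.
* Singular or ill-conditioned local systems (relative condition number
  above 1e10) fall back to degree 1, then to the tricube-weighted mean.
* Queries outside the fitted x range return NaN — curves are never
  extrapolated, at either the subject or the group level.
* Evaluation is strictly pointwise; there is no interpolation surface,
  so results are independent of any precomputation.

Defaults `span = 0.75`, `degree = 2` are the conventional loess
defaults; both are exposed everywhere. Exact numeric agreement with any
other loess implementation is not a goal — the statistical behavior of
the tests is what the suite verifies.

## Test statistics and nulls

**Group distance (permuspliner).** The statistic is the *sum* of
pointwise absolute differences over an `ints`-point grid (default
1000), not a trapezoid integral. On an even grid the sum is
proportional to the Riemann integral, so the choice only scales the
statistic — identically for observed and permuted values — and the
p-value is unaffected by `ints` except through grid resolution. The
grid spans the intersection of the two groups' observed x ranges and is
recomputed for each permutation from the permuted groups' overlap (the
no-extrapolation rule applied at the group level). Permutations whose
shuffled groups fail the `cut_sparse` threshold, cannot support a fit,
or have no overlapping range are redrawn rather than skipped, keeping
the permutation count constant; the redraw count is reported.

**Empirical p-value.** `p = (b + 1) / (m + 1)` with inclusive
comparison (ties count against rejection, conservative). The add-one
form never returns zero and makes the attainable floor `1 / (m + 1)` —
0.001 at the default 999 permutations.

**Per-interval test (sliding_spliner).** Mann–Whitney U, two-sided, is
the default because longitudinal biological variation is commonly
non-normal; Welch's t is available via `interval_test="welch_t"`. The
U test uses exact enumeration when both groups contribute ≤ 8 subjects
and there are no ties, otherwise the normal approximation with tie
correction (no continuity correction, so identical groups give
p = 1.0 exactly). A p-value is emitted at a grid point iff *both*
groups have at least `test_density` interpolated subjects there
(default 3). Raw p-values are returned without multiplicity adjustment;
callers who scan many intervals or many response variables should
adjust externally.

**Trend area (trendyspliner).** The baseline is the *flat* line through
the group spline's value at the first grid point: the null hypothesis
is "no meaningful increase or decrease", which a zero-slope reference
encodes without requiring a second anchor point. Permuted replicates
measure their area against the permuted spline's *own* start, so every
replicate is treated exactly like the observed data. Mean centering
(off by default; opt-in) replaces each `y` by `y - mean_s + grand
mean`, computed from the grand mean of all observations (not of subject
means — the two differ in unbalanced designs).

## Input handling

Tables are tab-delimited text with one header row (comma dialect
auto-sniffed). Rows with missing subject, or non-numeric/non-finite x
or y, are dropped and counted in a load report; zero and negative
responses are legal values. Category values are compared as exact
strings after trimming surrounding whitespace. `cut_low = n` keeps
subjects with *strictly more* than `n` observations (so `cut_low=1`
removes subjects seen only once — a deliberate reading of an
under-specified convention, stated in the CLI help). `cut_sparse`
defaults to 4 and is floored at 4 because a quadratic local fit is
underdetermined below 4 points.

## The synthetic-data generator

`simulate_perturbation_study` emulates a two-group perturbation
experiment: a control group of pure Gaussian noise (SD 1.0) around a
flat baseline, and a perturbed group with one or two localized Gaussian
bumps of amplitude `magnitude × noise_sd`, at magnitudes 1x/2x/4x. Ten
subjects per group, 30 jittered time points each on [0, 1]. The default
geometry — a single bump at x = 0.75 with width 0.05, or two
opposite-sign bumps at x = 0.60 and 0.75 — was chosen once so that the
magnitude sweep spans the interesting range: 1x sits near the detection
limit of the two-group test, 2x is reliably significant, and 4x
saturates the permutation floor; in the two-region scenario the
opposite-sign bumps are close enough that group-level smoothing
partially cancels them, making it the harder scenario at low magnitude.
`simulate_null` (identical noise in both groups, optional staggered
late entry) and `simulate_trend` (random intercepts plus a common
linear slope) provide the calibration cases for the two permutation
nulls and for mean centering.

What the generator does *not* emulate: compositional count data, zero
inflation, autocorrelated within-subject noise, or heteroscedastic
measurement error. Passing calibration and power checks on these
scenarios therefore demonstrates correctness of the algorithms under
clean exchangeable noise, not robustness to every pathology of real
microbiome data.

All generators are pure functions of their parameters and seed (NumPy
`default_rng`, PCG64).

## Verification and problem sizes

The test suite checks, among others: the loess engine against an
independently coded brute-force tricube WLS oracle (agreement to 1e-8;
exact recovery of constant/linear/quadratic data); the exact
Mann–Whitney enumeration against a combinatorial oracle; permutation
uniformity by chi-square; bit-for-bit reproducibility under a fixed
seed; group-label swap symmetry; and type-I-error calibration of both
permutation tests at α = 0.05 over 200 exchangeable-null replicates
(within the exact binomial 99% interval), run at reduced problem sizes
(8 subjects per group, 10 time points, 199 permutations, 150 grid
points) — type-I error under exchangeability does not depend on these
sizes, and the reduced runs keep the suite fast. The magnitude-sweep
power check (20 replicates per magnitude and scenario) likewise uses 99
permutations and a 200-point grid. Headline 4x results are computed at
the full defaults (999 permutations, 1000 grid points).

## Known limitations

* No robust (iteratively reweighted) loess; outliers can distort both
  the observed and permuted splines, especially in sparse data.
* The two-group test compares whole-trajectory distance; it has no
  covariate adjustment and no more-than-two-group omnibus form.
* The sliding test's per-interval p-values are *not* independent across
  the grid (neighboring intervals share subjects and smoothing), which
  is another reason the package leaves multiplicity handling to the
  caller.
* Group-level splines pool observations across subjects, weighting
  subjects by their number of observations; heavily sampled subjects
  influence the group curve more.
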