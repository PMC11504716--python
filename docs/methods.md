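# Methods

## Overview

`cranangles` implements a complete cranial-angle sex-estimation analysis:
36 angles computed from 3D landmark coordinates, per-angle dimorphism
testing, frequency-based attribute selection, and classifier evaluation
under repeated stratified cross-validation.  Because the CT-derived
coordinate data the analysis was designed for are not publicly deposited,
a synthetic-data module generates inputs with the statistical structure
the analysis assumes; its defaults are the study conditions (154 males,
180 females, prosthion missing in 18 males and 14 females, per-sex angle
moments from the packaged reference table).

## Landmarks and angles

The landmark registry has 26 named cranial points: 14 midsagittal, 11
bilateral, and the orbitale, digitized on the left side only — 37 point
slots after bilateral expansion.  Missing landmarks are first-class
(absent, never zero or NaN coordinates), because real material frequently
lacks the prosthion (damaged alveolar processes), which removes five of
the 36 angles for those specimens.

Two angle types are computed, both in degrees and both invariant under
rotation, translation and uniform scaling:

* **Line–plane angles** (20 measurements): the acute angle between a
  landmark-defined line and the Frankfurt horizontal (FH) plane through
  left orbitale, left porion and right porion.  With unit plane normal
  `n` and line direction `d`, the reported value is
  `90° − arccos(|d·n| / ‖d‖)` — the angle to the *plane*, range [0, 90].
  The underlying dot-product formula measures the line–normal angle; the
  complement is reported because reference values such as the foramen
  magnum tilt (≈7°) are plainly plane-relative.  The absolute value makes
  the result independent of normal orientation and of landmark order.
* **Two-line (three-point) angles** (16 measurements): the vertex angle of
  the triangle spanned by three landmarks, from the Law of Cosines on the
  side lengths, range [0, 180].  The vertex is the middle-named landmark.
  Transversal angles use (right, vertex, left) ordering; the value does
  not depend on it, but the order is fixed for reproducibility.

Cosine arguments are clamped to [−1, 1] before `arccos`; clamps are
counted and any excursion beyond 1e−12 raises an error rather than being
silently absorbed.  All computation is double precision; no intermediate
rounding is applied, so results can differ from workflows that round side
lengths before the angle step by below 0.01°.

**Intraobserver error** is the standard deviation of repeat digitizations
of a landmark: the square root of the summed per-axis sample variances
(divisor n−1).  This matches the common single-number "within 1 mm"
convention; per-axis SDs are available via `per_axis=True`.  The measure
is invariant under rigid motion of all trials jointly.

## Dimorphism testing

Per angle, both sex samples are screened with Shapiro–Wilk (normality,
per sex) and Levene's test (variance equality, centered on the mean by
default).  The pooled two-sided t-test is used only when both samples
pass normality *and* variances are equal at the screening level (0.05);
otherwise the two-sided Mann–Whitney U-test is applied (asymptotic with
tie and continuity correction — appropriate at n ≈ 150 per group).  This
conjunction is the most conservative standard reading of the two-stage
protocol; the truth table is frozen in the tests and each leg is
configurable (Welch t, median-centered Levene, exact U).  No multiple-
testing correction is applied by default, matching the 36-raw-tests
design; Holm adjustment is available but off.

A caveat frozen into the test suite: simulated data drawn from the
*summary* moments of the reference table cannot reproduce every
significance flag per replicate.  Several significant angles have
standardized mean gaps of only z ≈ 2.2–3.1, i.e. per-replicate power
0.6–0.9, and one angle (the nasal-bone projection angle rhi-n-pr) is
significant by the U-test with practically equal means — its signal lives
in distribution shape the summary statistics do not carry.  The tests
therefore assert flag recovery only where z ≥ 4.

## Feature selection

CFS merit: `merit(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff)` with attribute–class
and attribute–attribute correlations measured as symmetrical uncertainty
`SU = 2·I(X;Y)/(H(X)+H(Y))` over discretized attributes.  Discretization
is recursive entropy minimization with the MDL stopping rule; attributes
for which no split is accepted carry SU = 0 and are flagged.  Missing
cells are excluded pairwise.

The best subset is found by forward best-first search from the empty set
with a priority queue of open states and a backtracking stale limit of 5
consecutive non-improving expansions (a widely used default).  Tie-breaks
follow attribute registry order, making the search deterministic.  On CFS
models built from data the search attains the exhaustive-search optimum
(verified over 200 random ≤12-attribute models); adversarially chosen
abstract correlation matrices that no dataset realizes can defeat any
bounded-backtracking heuristic, and are not the intended input.

Attribute importance (AI) is the selection frequency over the training
sides of a repeated stratified plan (10 repeats × 5 folds = 50 runs; each
training side holds 80% of the examples).  Randomness enters only through
fold assignment; the search itself is deterministic.  Thresholded subsets
(>0, ≥0.1, ≥0.3, ≥0.4, ≥0.6, ≥0.9, =1 by default) are nested by
construction.  A reference transcription of the originally reported AI
subsets ships with the package for comparison; it is never consulted by
the selection algorithm.

## Classification

All classifiers share one repeated stratified 5-fold plan (per class,
fold sizes differ by at most one).  Reported measures: overall accuracy
and per-class accuracy (male/female recall), averaged over all repeats
and folds.  The majority baseline at the default class sizes is
180/334 = 0.539.

* **CN2** (implemented natively): beam search (width 5) over conjunctions
  of threshold conditions; candidate thresholds are boundary midpoints;
  rule quality is Laplace accuracy `(correct+1)/(covered+2)`.  Default
  variant is *unordered* per-class set covering — covered positives are
  removed, negatives kept — with prediction by correct-coverage-weighted
  voting; an *ordered* sequential list with default rule is provided.
  `min_coverage` (default 15) filters rules to at least that many
  correctly covered training examples; per class, any positives left
  uncovered when no admissible rule remains are recorded as a remainder.
* **SVM**: RBF kernel.  By default (C, γ) are picked once by a grid
  search with internal stratified CV on the full dataset before the first
  evaluation run, reproducing a fixed-up-front protocol; this search sees
  the evaluation data, so a leak-free per-training-fold search is
  provided (`svm_per_fold=True`) and recommended when absolute accuracy
  matters.  Features are standardized with training-fold statistics.
* **Naive Bayes**: on MDL-discretized attributes with Laplace smoothing
  by default; Gaussian NB as option.
* **Logistic regression**: effectively unregularized (ridge C = 1e6 for
  numerical safety under separable data).

Missing values are median-imputed from the training fold; a complete-case
analysis can be run by dropping rows beforehand.  The imputation choice is
recorded in every evaluation's notes.

## Synthetic data

Two generators, both fully seed-deterministic:

* **Angle-table generator**: per sex, multivariate normal draws with the
  packaged per-sex means and SDs.  Inter-angle correlations are not
  published, so the default is independence, with an exchangeable-ρ or
  user-matrix option; this choice bounds the achievable classifier
  accuracy and is deliberately conservative.  `effect_scale`
  interpolates per-sex means toward the pooled mean (0 = exact null).
  Truncation to the printed min/max is off by default (truncation shifts
  moments); when on, independent draws are resampled per cell and
  correlated draws clipped.  Prosthion-dependent angles are blanked at
  the observed per-sex rates (18/154, 14/180).
* **Landmark generator**: per-sex mean landmark templates were calibrated
  offline by least squares so that each sex's template reproduces the
  per-sex reference mean angles (midsagittal landmarks pinned to y = 0,
  FH plane to z = 0, bilateral landmarks mirror-symmetric; bilateral
  angle targets use the R/L average).  Residuals are < 0.4° for 33 of 36
  angles; the three mutually coupled nasal-profile angles (n-ss-FH,
  n-rhi-FH, rhi-n-ss) retain ~2° residuals because their printed means
  are not exactly co-realizable by a single configuration — averages of
  nonlinear angle functions do not commute with the angle of the average
  configuration.  A specimen is `neutral ± effect_scale·displacement`
  (the displacement field is half the difference of the sex templates;
  its dominant components are glabella protrusion, forehead inclination,
  inion protrusion, and nasal-aperture width), plus isotropic Gaussian
  digitization noise and an optional uniform random rigid transform.

  The noise default is 0.3 mm per axis (≈0.52 mm 3D SD, within the
  ≤1 mm error bound the acquisition-error analysis established).  It was
  calibrated against the generator contract that draws near the mean
  male configuration stay within the per-sex reference ranges for ≥95%
  of specimens: the near-straight nasal-curvature angle n-mn-rhi has a
  geometric sensitivity of roughly 8°/mm of transverse midnasale jitter
  (its two segments are only 10–14 mm long), so 0.5 mm noise would give
  that angle more spread than its biological SD.  The templates are
  synthetic and make no anatomical claim beyond plausible angle ranges
  and the observed direction of dimorphism.

What the generators do *not* emulate: inter-angle correlation (real
angles sharing landmarks are strongly dependent), measurement error
correlated across angles, asymmetry, age structure, and population
heterogeneity.  Passing tests on synthetic data therefore validate the
machinery — geometry, test selection, search, CV plumbing — not the
real-data accuracy figures, which require the original material.

## Pipeline and problem sizes

Stage order: angles → dimorphism → restriction to significant angles →
repeated selection on the restricted table → evaluation of every
classifier on every non-empty thresholded subset (plus the full
significant set) → report with full config/seed provenance.  Identical
config and seed reproduce the report bit-for-bit.  With no significant
angles (e.g. `effect_scale=0`), selection and evaluation are skipped and
the report carries the baseline only.

Default problem sizes used by the packaged analyses and checks: full
cohorts of 334 specimens for single evaluations; 200 replicates for the
null-calibration rate; reduced cohorts (≈50–130 specimens, 2 repeats)
for structural and determinism checks, where the property under test
does not depend on sample size.

## Known limitations

* Decision-rule details the original environment did not print (exact
  NB/LR defaults, the SVM search grid, the Levene centering) are
  reconstructions; each is configurable and documented where it appears.
* The U-test branch uses the asymptotic normal approximation; exact
  enumeration is impractical at n ≈ 150 and unnecessary there.
* The unordered CN2 voting scheme resolves conflicts by correct-coverage
  sums, one of several conventions in use.
* Real-data accuracies cannot be reproduced without the original CT
  material; all reported numbers here are synthetic-data results.
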