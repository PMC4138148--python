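# Methods

## Scientific setting

Children living beside informal electronic-waste (e-waste) recycling
workshops ingest lead from dust, soil and hand-to-mouth activity.  The
package analyses a child-level survey of the kind used to study this
exposure: two residential areas (one adjacent to e-waste recycling, one
comparable reference area), measured blood lead level (BLL, µg/dL),
anthropometrics, and ~25 coded lifestyle / household questionnaire items.
The outcome of interest is *elevated* BLL, defined inclusively at the CDC
action level of 10 µg/dL.

The analysis has three layers:

1. **Descriptive epidemiology** — characteristics cross-tabulated against
   the elevated/non-elevated stratum (Pearson chi-square without continuity
   correction), elevated proportions over non-missing denominators, pooled
   t-tests on ln(BLL), within-area Mann–Whitney comparisons of boys and
   girls, and an ANCOVA of ln(BLL) on area adjusting for age, height and
   weight.  BLLs are right-skewed, so location is summarized as median
   (IQR, quartiles by linear interpolation) and all parametric comparisons
   act on the natural log; t, U and F statistics are invariant to the log
   base.
2. **Group-Lasso logistic regression** — each k-category questionnaire item
   is dummy-coded into k−1 indicators referenced on its first category, so
   an item enters or leaves the model as a whole group.  With groups
   g = 1..G of size df_g, the estimator minimizes

       (1/n) Σᵢ [log(1 + exp(ηᵢ)) − yᵢηᵢ] + λ Σ_g √df_g ‖β_g‖₂ ,
       η = β₀ + Xβ,

   the intercept unpenalized.  λ is tuned by 10-fold cross-validated
   binomial deviance; an unpenalized all-covariate logistic fit (Wald
   odds ratios with 95% CIs) is reported alongside as the conventional
   comparison.
3. **Resampling validation** — per-group selection frequencies of the full
   CV-tuned pipeline over bootstrap resamples (robustness) and over
   outcome-permuted stratified subsamples (negative control), each at
   N ∈ {150, 200, 250} with B = 100 replicates.

## Optimization

Group descent with a majorize–minimize step per block.  The logistic-loss
curvature is globally bounded by 1/4, and each group block is centered and
orthonormalized (Xᵍᵀ Xᵍ / n = I via the Cholesky factor of the group Gram
matrix), so the block update is the exact closed-form group soft-threshold

    z_g  = β_g + (4/n) X_gᵀ(y − p),
    β_g ← max(0, 1 − 4λ√df_g / ‖z_g‖₂) · z_g .

Every block update decreases the convex objective (monotone descent is
asserted in tests), and the fit carries a KKT certificate: at convergence
the per-observation score of each active group has norm λ√df_g and each
inactive group's score norm is below that bound (tolerance 1e−6 in tests).
The orthonormalizing transform is recorded so coefficients map back to the
original covariate scale exactly; odds ratios are exp of original-scale
coefficients.

Numerical choices: convergence when the largest standardized-coefficient
change over a sweep is below 1e−6 (1e−5 inside resampling replicates);
max 1000 sweeps (500 in replicates); λ grids are log-spaced from λ_max =
max_g ‖X_gᵀ(y − ȳ)‖/(n√df_g) down to a ratio of it (default 100 points to
0.001·λ_max); warm starts along the path; CV folds stratified on the
outcome, deviance-minimizing λ with ties broken toward the larger
(sparser) value; probabilities clipped to [1e−12, 1−1e−12] in the
deviance.  Standardization is recomputed inside every CV training split so
no held-out information leaks into the transform.  The ordinary Lasso is
the special case in which every group is a singleton.  A numba-compiled
kernel runs the identical sweep schedule for path fits; the pure-Python
implementation remains the reference and the two agree to the tolerance.

The unpenalized reference fit uses Newton/IRLS (statsmodels), retrying
with L-BFGS before declaring separation; with ~72 columns on a few hundred
records that model is intentionally fragile — which is the argument for
the grouped penalty.

## Synthetic survey generator

The original survey data were never deposited, so the pipeline ships a
seeded generator that emulates the study's structure; its defaults are the
study conditions.

* **Instrument**: 31 covariates — 4 continuous anthropometrics plus 27
  categorical items (7 binary, 2 three-level, 16 four-level, 1 five-level,
  1 six-level), expanding to 72 design columns.  Item wording is generic;
  the category-count structure is what matters to the model.
* **BLL margins**: per-area log-normal with medians (IQRs) 7.06 (4.71) and
  5.89 (3.54) µg/dL.  (log-mean, log-sd) solve median = exp(µ) and
  IQR = 2·median·sinh(z₀.₇₅σ) — a closed form confirmed by a bracketed
  root-find.
* **Outcome mechanism**: P(elevated) = logistic(β₀ + xᵀβ_true) on the
  dummy scale, defaults ln(0.51) for girls and ln(2.28) for e-waste
  workshop within 50 m, all other groups zero.  Elevated status is drawn
  first; BLL is then drawn from the matching truncated region of the
  area's log-normal (≥10 µg/dL when elevated).  When the mechanism's mean
  event rate equals the log-normal mass above 10 µg/dL the marginal BLL
  distribution is exactly the untruncated log-normal, so the continuous
  margins and the odds-ratio structure hold simultaneously.  By default
  the intercept is calibrated (1-D root-find on the realized sample) to
  that exceedance mass; an explicit intercept is honored as given.
* **Missingness** is missing-completely-at-random per field, mirroring
  questionnaire columns whose counts sum below the stratum size.
* Default sample: 842 children, 61% in the exposed area; the risk-factor
  analysis runs on exposed-area complete cases (the published analysis
  used 334 validated questionnaires, and the recovery experiments below
  use that n).

What the generator does **not** emulate: household/sibling clustering,
correlation between the continuous age and the categorical age band (and
between anthropometrics), dose–response between covariates and the
continuous BLL beyond the threshold coupling, and any informative
missingness.  Passing tests therefore certify the statistical machinery
under a faithful but idealized independence structure, not performance on
real field data.

Rare categories (e.g. a 0.4% maternal-illiteracy reference level) can be
unobserved in a subsample, which leaves a dummy block collinear after
centering.  Model-fitting code paths that face subsamples (pipeline fits,
CV training splits, resampling replicates) drop within-group dependent
columns via pivoted QR and proceed; direct encoding is strict and raises a
group-named error.

## Resampling schemes

Bootstrap replicates draw N records with replacement (unstratified).
Inside a replicate the CV folds are *group-aware*: copies of the same
source record always share a fold, otherwise duplicated observations leak
across the train/test split and CV tunes λ toward zero (every group ends
up "selected" in most replicates).  The
permutation scheme draws a stratified subsample of size N that preserves
the overall elevated proportion, then permutes the outcome labels within
the subsample, fixing class counts exactly — this satisfies both readings
of "fixing the proportion during resampling".  Every replicate re-runs
encoding, standardization and CV tuning; replicate seeds derive from the
master seed by a counter, so results are independent of execution order.
The negative-control check asks, per group, whether its selection count
significantly exceeds the across-group mean frequency (one-sided binomial
test at α = 0.01).

## Problem sizes used in the shipped checks

The worked-example checks run on the published count tables directly.
Calibration checks use n = 10⁵ (margins) and n = 10⁴ (effect recovery by
MLE).  Recovery and stability experiments run the full CV-tuned pipeline
at n = 334 with a 40-point λ grid down to 0.01·λ_max, B = 100 replicate
bootstrap/permutation runs at N = 250 in the test suite (the acceptance
script uses B = 50 and 30 recovery replicates); the analysis scripts use
the full B = 100 at all three N values.

## Known limitations

* **CV-min selection is noisy at this scale.**  With 31 candidate groups
  on ~334 records, the deviance-minimizing λ occasionally lands far down
  the path (overselecting on pure noise) or above the signal groups'
  activation point.  Measured over 100 seeded replicates of the default
  conditions, the tuned active set contains the e-waste group in ~90% and
  both true groups in ~75% of replicates; the sex effect (|z| ≈ 2.3 at
  n = 334) is the bottleneck, and no tuning-free selector could contain it
  near-certainly at that signal strength.  On pure noise the selected
  model keeps ≤1 group in ~72% of replicates.  The one-standard-error
  rule would stabilize the null behaviour but is deliberately out of
  scope (the analysis uses the strict minimum).
* Bootstrap frequency ranking is far more stable than any single fit: the
  two true groups rank top-2 by a wide margin in the default conditions.
* **Null selection is not exchangeable across item types.**  Under
  permuted outcomes the group score norm of a rare binary item (e.g. 10%
  prevalence) has a heavier right tail than that of balanced items, so
  such items are picked somewhat more often than the across-group mean
  even with the √df penalty calibration.  A per-group binomial test
  against the mean selection frequency can therefore flag a rare binary
  item on pure-noise data; this is a property of the selector, not
  evidence of association.
* The ANCOVA adjusts three covariates linearly on the log scale; no
  interactions or splines.
* Ordinal items are penalized as unordered dummy groups (no score
  coding), matching the modelling choice the analysis reproduces.
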