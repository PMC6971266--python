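# Methods

## The problem

High-dimensional biomarker studies (the motivating case is radiomics, where
hundreds to thousands of quantitative features are extracted from annotated
regions of medical images) are routinely confounded by acquisition and
annotation factors: scanner model, imaging parameters, rater identity.  A
*side study* — a small scan-rescan or annotate-reannotate experiment —
quantifies how much each feature moves when the confounder changes, but the
main study's labels and the side study's stability information live in
different datasets.  The common remedy, deleting every feature whose
stability falls below a threshold, throws away predictive information along
with the noise.  This package implements the alternative: estimate a
per-feature noise model from the side study and *augment* the main study's
training data with that noise, so that embedded feature selection can weigh
a feature's informativeness against its instability.

## Noise model and estimators

The confounder's effect on feature j is modelled as additive Gaussian noise,
and the augmentation transform is

    Θ(x | μ, σ²) = x + ε,   ε_j ~ N(μ_j, σ²_j)  independently per feature,

with one fresh draw per augmented copy.  The model is per-feature: no
cross-feature covariance is estimated (side studies are far too small for a
4000×4000 covariance), and none is injected.

* **Paired side study** (same subjects under both confounder values):
  μ_j and σ²_j are the mean and sample variance (denominator m−1) of the
  per-subject differences b−a.  The sample variance is used because side
  studies are typically small and the unbiased estimator matters there.
* **Unpaired side study** (two cohorts split by confounder value):
  μ_j is the difference of group means; σ²_j is the *sum* of the two group
  variances, the variance of a difference of independent measurements.
  This estimator deliberately accumulates the within-group biological
  variance of both cohorts and is therefore inflated relative to the paired
  one; it is the honest attainable estimate without pairing.

The sign of μ follows the convention "group b minus group a"; which group is
the main study's own acquisition condition is the caller's responsibility
(the CLI asks for it implicitly through file layout).  `NoiseModel.symmetrized()`
zeroes μ and keeps only σ² for cases where the direction is unknown.
Simulation studies may bypass estimation entirely and inject the generating
noise model (`source_mode="known"`), which is how the synthetic benchmark is
evaluated by default — it isolates the value of the information transfer
from side-study sampling error.

## Stability filters (the baseline)

* **CCC filter** (paired data): Lin's concordance correlation coefficient
  per feature, computed with population (1/n) moments,
  CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²); features with CCC < τ_CCC are
  removed.  τ_CCC defaults to 0.8, the conventional agreement cut-off in
  reproducibility work.  Degenerate columns are handled deterministically:
  two identical constant vectors agree (CCC 1, kept); constant vectors with
  different means do not (CCC 0, removed).
* **t-test filter** (unpaired data): two-sided two-sample t-test per
  feature, Welch's unequal-variance form by default (two confounder groups
  carry no equal-variance guarantee; a pooled-variance flag exists);
  features with p < τ_test are removed, with *no* multiple-testing
  correction — the threshold is used as a probability cut-off, not a
  significance test.  τ_test defaults to 0.05.  Constant-equal columns get
  p = 1 (kept), constant-unequal p = 0 (removed).
* **Multi-repeat designs** (more than two measurements per subject) are
  collapsed by averaging CCC over all unordered pairs of repeats
  (`ccc_filter_repeats`); this is a convention of this package, chosen over
  designating two arbitrary repeats.

The normality diagnostic (`normality_diagnostic`) checks the Gaussian noise
assumption: Shapiro–Wilk per feature on the paired differences, with a
Bonferroni-adjusted level α/n_features.

## Augmentation

Each training observation is replaced by `copies_per_observation` (default
2) noisy copies; labels are copied along.  The originals are *not* kept by
default — the augmented set stands in for the main study — but
`include_originals` exposes the alternative.  Noise is applied to raw
feature values; any standardisation is the classifier adapter's concern
(the LASSO pipeline standardises inside the training fold).

SMOTE is implemented internally (classic form: convex interpolation
x + u·(z−x) toward one of the k = 5 nearest same-class neighbours,
Euclidean distance on raw features) so the neighbour rule and RNG are
pinned; it exists purely as the sample-size control, adding rows that carry
no confounder information.

## Synthetic benchmark

The generator emulates a two-class radiomics-scale study: per feature a
base distribution N(m_j, s_j²) with m_j ~ U(−1, 1) and s_j ~ U(0.5, 2);
20 of 4000 features are informative, their class-1 mean displaced by one
base standard deviation; 150 training observations per class drawn without
confounder shift; 500 test observations per class with every feature
shifted by a systematic per-feature offset δ_j ~ N(0, 1) plus
per-observation noise of standard deviation σ_j ~ U(0, 1).  A paired side
study draws class-0 subjects and re-measures them under the shifted
condition; an oracle pool draws labelled observations under the shifted
condition.  A skew-normal noise family (shape `skew_alpha`) is available as
a stress test of the Gaussian assumption; at shape 0 it reduces exactly to
the normal family.

The hyper-ranges above are this package's choices, exposed in
`BenchmarkConfig`: what matters for the qualitative strategy comparison is
that (i) informative features are a small minority, (ii) the confounder
perturbs features regardless of informativeness, and (iii) the shift is
comparable in magnitude to the biological signal.  Exact feature-retention
counts do depend on these hyperparameters and should not be read as
universal.

What the generator does **not** emulate: correlation between features
(radiomics features are heavily collinear), multi-rater geometry,
non-additive confounder effects, and label noise.  Passing benchmarks here
therefore demonstrates the mechanics and the direction of the effects, not
effect sizes on any particular real dataset.

## Evaluation protocol

A study bundle contains the side study (split A), the labelled main study
(group B1), optionally an extra labelled pool containing the confounder
variation (rest of split B, used only by the oracle strategy), and one or
more confounder-shifted labelled test groups (split C).  Per strategy ×
classifier run:

1. Training pool: B1, or B1 ∪ extra for the oracle.
2. Stable set (filtering/combined) and noise model (proposed/combined) are
   computed from the side study only — never from training or test rows.
3. Outer 5-fold stratified CV.  Within each fold, the strategy processes
   the fold-training rows only (column subset for filters; augmentation;
   SMOTE sized to match the augmented row count), hyperparameters are tuned
   by an inner 3-fold stratified CV maximising AUC, and the fold model
   scores the held-out rows.  `cv_auc` is the mean fold AUC — the estimate
   a practitioner would report.
4. The model is refit on the full processed pool and scored on every test
   group; the absolute estimation error is AEE = |cv_auc − min test AUC|.

One deliberate subtlety: for strategies that augment, the held-out fold
rows are scored after **one fresh draw of the noise transform**.  A
practitioner applying this method cross-validates the augmented dataset,
so their held-out observations carry the confounder noise; scoring
untouched rows instead would make the CV estimate measure the *unshifted*
condition while the model is adapted to the shifted one, producing a large
estimation error by systematic under-estimation.  Drawing fresh noise per
held-out row preserves that estimand without sharing any parent row
between training and validation.  Non-augmenting strategies score untouched
rows.

Classifiers: random forest (500 trees by default; grid over max_features
{√n, 0.1n} and min leaf {1, 5}), gradient boosting (grid over trees
{100, 300}, learning rate {0.05, 0.1}, depth {2, 3}), and L1-penalised
logistic regression (10-point C path, standardised within fold).  Grids
are deliberately small and overridable per run; tuning is independent per
strategy.  Feature importances come from impurity importances (trees) or
absolute standardised coefficients (LASSO), ranked with a stable sort.

AUC is the Mann–Whitney probability that a positive outscores a negative,
ties counting one half.  Uncertainty on repeated runs is summarised by
percentile bootstrap 95% intervals of the mean.  A run whose filter removes
every feature is reported as a flagged failed row, not an exception.

All randomness is threaded from explicit seeds through
`numpy.random.SeedSequence`; identical seeds give identical results
(classifier internals are seeded and single-threaded).

## Problem sizes used by the acceptance script

`scripts/acceptance.py` runs the strategy comparison at a reduced scale —
1000 features (20 informative), 150 training observations per class, 200
test observations per class, 10 repeats, random forest (100 trees) and
gradient boosting (depth 2, feature subsampling), nested tuning over
two-point grids — chosen so a complete run finishes on a single CPU in
roughly a quarter of an hour.  The strategy ordering (estimation error:
ignore > filter > augment; model power: augment ≥ filter) is stable at this
scale; the estimator and filter calibration checks run at the sizes stated
in their docstrings (10⁵ pairs/copies, 1000 null features).

## Known limitations

* The noise model is additive, Gaussian and feature-independent; real
  confounder effects can be multiplicative, skewed (the skew-normal
  generator family probes this) and correlated across features.
* The unpaired estimator over-states σ² by construction (Bienaymé sum of
  within-group variances); with it, augmentation injects more noise than
  the confounder actually causes.
* Only binary targets and two confounder values are supported; multi-level
  confounders and multi-class outcomes are out of scope.
* AEE uses the minimum test-group performance; with many small test groups
  it is a conservative, noisy criterion.
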