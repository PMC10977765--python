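# Methods

This note documents the statistical procedures `remisml` implements, the
generative model behind its synthetic cohorts, the numerical choices made
where the design was genuinely open, and what the package's tests do and do
not establish about real clinical data.

## Outcome and cohorts

The outcome is week-8 remission of major depressive disorder, defined as a
17-item Hamilton Depression Rating Scale (HDRS-17) total of at most 7 after
eight weeks of treatment. The package's containers model two-study designs:
a small single-site randomized trial (n ≈ 85, SSRI vs placebo) used for
training and internal cross-validation, and a larger four-site trial
(n ≈ 197) used for external validation, harmonized to a shared feature set
of structural-MRI morphometrics (measures × 68 cortical regions),
questionnaire items (HDRS, QIDS) and clinical/demographic covariates.
Remission labels are never stored; they are always derived from the week-8
score so the two cannot drift apart.

## Synthetic cohort generator

The generator emulates the statistical structure this analysis assumes, not
any particular dataset:

- **Imaging block.** Each feature is one (measure, region) pair. A
  participant-level region latent is shared across measures, giving
  cross-measure correlation ρ (default 0.3, configurable in [0, 1)) within a
  region and independence across regions. All features are unit-variance
  Gaussian before site effects.
- **Site heterogeneity.** Each (site, imaging feature) pair receives a mean
  offset drawn once per cohort as `magnitude × N(0,1)`. Offsets are added to
  the *observed* values only — the latent outcome model sees the pre-offset
  "biological" values — so the shift acts as pure measurement heterogeneity
  (the scanner/site analogy). Offsets are drawn before participant data, so
  at a fixed seed the same offset pattern rescales continuously with the
  magnitude; between-site distance is exactly monotone in it.
- **Questionnaire items.** A latent severity factor per participant drives
  all ordinal items (loading 0.6), which are thresholded latent Gaussians cut
  at equal-mass quantiles and bounded (HDRS items 0–2, QIDS items 0–3); the
  baseline HDRS total is their sum, treated as continuous.
- **Outcome model.** A latent score s = Σβⱼ·(biological imaging value)ⱼ +
  0.5·severity + ε, ε ~ N(0,1). Five imaging features in distinct regions
  carry the default signal (β = 0.8 each). Because every term is Gaussian
  with known covariance, s is exactly N(0, σ²) and the remission threshold is
  placed analytically at the target-prevalence quantile (default 0.37);
  the week-8 HDRS is `clip(floor(8 + 4·(s − τ)), 0, 52)`, so remission
  (score ≤ 7) occurs exactly when s < τ. Prevalence is therefore calibrated
  by construction, not by simulation.
- **Missingness.** Feature cells are MCAR at a small rate (default 1%).
  Outcome missingness is MAR by default: a logistic model on the observed
  baseline severity, with the intercept solved (Brent's method) so the mean
  missingness probability equals the configured rate (defaults ≈ 8% for the
  single-site study, ≈ 25% for the multi-site study, mirroring the
  frequencies such trials report).

What the generator does **not** emulate: real morphometric covariance
structure (it is exchangeable across regions), item-level measurement
idiosyncrasies, treatment-by-site interactions, longitudinal HDRS
trajectories, or any nonlinear feature-outcome relation. Tests that pass on
these cohorts therefore establish the *procedures* are implemented correctly
and behave as theory predicts — not that any particular real dataset would
yield similar numbers.

## Pre-processing

- **Measure pruning.** For every pair of imaging measures, Spearman's ρ is
  computed per region between the two measures' region columns and |ρ| is
  averaged over regions. Measures are retained greedily in sorted order;
  a measure is kept only if its average |ρ| with every already-kept measure
  is below 0.7. We use |ρ| because a strongly negative duplicate is equally
  redundant, and keep-first in canonical order because no retention rule is
  canonical; both choices are documented, deterministic and idempotent.
- **Feature filters.** Single observed category (any kind); any observed
  category with count ≤ 3 (categorical/ordinal/binary kinds); missing
  fraction above a threshold defaulting to 0.2 ("too many missing values"
  has no canonical cutoff; 20% is configurable).
- **Standardization.** (x − μ)/σ for continuous features with μ, σ from the
  training partition only, σ with the population denominator n (fixed for
  bit-reproducibility, matching common ML-toolkit scaling). Zero-variance
  training columns map to 0 in both partitions with a logged warning.
  Ordinal/binary features pass through.

## Multiple imputation

M = 10 by default. Conditional models are Bayesian ridge regressions inside
a chained-equations sweep (10 iterations) drawing from the posterior
predictive, which is well-posed when features outnumber participants; an
optional cap on predictors per conditional model (`n_nearest_features`)
trades fidelity for speed on wide data. Integer-valued features are rounded
to the nearest integer and clipped to their observed bounds after
imputation; the week-8 score is imputed jointly with the features, rounded,
clipped to [0, 52], and remission is then derived per imputation — this
order (impute the score, then derive the label) is deliberate. Observed
cells are restored bit-identically in every imputation. When a training and
an external study are analyzed together they are imputed jointly by default
(all participants in one model), with per-study imputation available by
simply imputing each cohort separately.

## Consensus feature selection

For every imputation × repeat × fold × model, the model is fitted on the
fold-training part (standardized within the fold) and its top-k (default
20) features by importance are recorded: absolute coefficients for
penalized regressions, impurity importances for tree ensembles, permutation
importance (mean ROC-AUC drop over shuffles) for SVM and neural network.
The tally over all M·R·K·|models|·k entries (30,000 at the full-scale
settings) is sorted by frequency, ties broken by name, and the top `keep_n`
(default 50) names form the selection. Selection-stage fits use fixed small
hyperparameters — the nested search belongs to the modeling stage only.

Two leakage modes exist because the once-per-training-set selection that
precedes CV evaluation is optimistic: the default `per_fold` mode reruns the
consensus on each outer-training partition, while `global` mode selects once
on the full training stack. The experiment drivers default to `global` mode
so the optimism of that once-per-training-set design can itself be studied
end to end.

## Modeling and stacking

Evaluation is R-repeated K-fold CV (defaults 5 × 4); each outer-training
partition tunes every base learner by an inner stratified 3-fold grid
search over small documented grids (penalty strength over log-spaced values
with l1/l2/elastic-net as one grid dimension; tree depths {2, 3, 4}; SVM C;
network width and weight decay), then refits on the full partition. A
single-configuration grid short-circuits to a plain fit. Stacking trains an
unpenalized logistic meta-model on base-model probabilities — out-of-fold
probabilities by default (anti-leakage), resubstitution probabilities
optionally — in two variants: all six bases, or penalized logistic +
neural network only. External validation refits on the complete training
study per imputation and predicts the paired test-study imputation. Hard
labels use a 0.5 threshold (configurable); no class reweighting is applied.

## Evaluation and pooling

Remitter is the positive class. Zero-denominator metrics (e.g. PPV with no
predicted positives) are reported as undefined and excluded from pooling
for that imputation, never coerced to 0. For the internal-CV role,
repeat-level metrics (each repeat scores every participant exactly once out
of fold) are averaged within imputation; the M per-imputation estimates are
combined by Rubin's rules — W the mean within-imputation variance, B the
between-imputation sample variance, T = W + (1 + 1/M)B, Wald 95% CI
estimate ± 1.96√T. Within-imputation variances use the binomial form
p(1 − p)/n (metric-specific denominators) for proportion metrics and the
bootstrap variance (participant-level resampling, 1000 resamples by
default, single-class resamples redrawn) for the AUC. For the external
role, proportion metrics use sd/√M across imputations; the notation "σ/n"
sometimes used for that quantity is read as the standard error of the mean
σ/√n, with the literal σ/n reading available behind a flag.

## Subgroup ROC analysis and p-value combination

Per subgroup and imputation, sensitivity and specificity are computed at
every threshold of a fixed descending grid (default 10,001 points from 1 to
0, preceded by an above-one sentinel so the (0,0) corner is always present;
predicted positive when probability ≥ threshold), along with the AUC;
curves and AUCs are averaged across imputations at fixed thresholds.
Imputations where a subgroup has a single class are skipped with a warning;
levels below 10 members are dropped.

Groups are compared with an L1-type statistic: the sum over groups of the
integrated absolute difference, on a common false-positive-rate grid (201
points), between the group's empirical ROC step function and the pooled
ROC. The null distribution permutes group membership (label–score pairs
stay together; default 999 permutations); the p-value uses the add-one
convention (1 + #{permuted ≥ observed})/(1 + B), which avoids exact zeros
and leaves the degenerate-copies case at p = 1. The M dependent p-values
are combined as the harmonic mean p-value p̃ = (Σωᵢ)/(Σωᵢ/pᵢ) with equal
weights; the asymptotically-exact tail correction from the HMP literature
is intentionally not applied — the raw combination is the documented
procedure here. Baseline-severity subgroups use a median split unless
cutoffs are supplied.

## HDRS factor scores

Five published symptom factors with fixed loadings are provided (psychic
depression, loss of motivated behavior, psychosis, anxiety, sleep
disturbance), each with an arithmetic sum and a load-weighted sum. The
published anxiety-factor weighted-sum formula uses item 19 where the
factor's item list has item 09; `hdrs_factor_definition("F4", ...)`
implements the formula exactly as published by default and exposes an
`item09` variant.

## Experiment designs and problem sizes

Three designs: single-site → multi-site external validation, the reverse,
and a pooled 2/3–1/3 split (fixed across imputations, stratified by study
and observed remission — the stratification is our choice; none is
canonical). The packaged demonstration runs use desk-scale problem sizes
chosen as this package's own defaults for simulation studies: M = 3,
R = 2, K = 4, 48 imaging features, n = 96 vs 160, and an ultra-light sweep
variant (M = 2, penalized logistic only) for magnitude × seed grids. In the
collapse demonstration the generator's severity effect is set near zero so
the outcome signal is carried almost entirely by the imaging features the
site offsets act on — that is what makes the constructed shift hit the
whole signal; with the default severity effect the questionnaire channel
transfers across sites and floors the external AUC near 0.6. The "strong
shift" magnitude (6 biological SDs) is deliberately extreme: it represents
the regime where between-site measurement differences dominate the
biological signal.

## Numerical and reproducibility notes

- Every stochastic component takes a seed; derived seeds are produced with
  `numpy.random.SeedSequence` and kept below 2³¹. Identical configurations
  reproduce outputs bit-identically.
- Importance ties at selection break by canonical column order (stable
  argsort); tally ties break by name.
- Fold assignment permutes participants and splits into K near-equal blocks
  (sizes differ by at most 1).
- AUC is the rank statistic with ½ for ties, cross-checked in tests against
  exhaustive concordant-pair counting.

## Known limitations

- The imputation model is linear-Gaussian per conditional; rounding imputed
  ordinals (rather than predictive mean matching) can distort ordinal
  distributions when missingness is heavy.
- The bootstrap AUC variance ignores the fold structure of CV predictions;
  within-imputation variance for proportion metrics assumes independent
  Bernoulli trials.
- The permutation ROC comparison treats groups as independent samples;
  applying it to subgroups that share fitted models is the documented
  procedure, but the independence assumption is approximate there.
- The generator's exchangeable covariance makes consensus selection easier
  than on real morphometrics, where correlated regions compete for rank;
  recovery rates reported by the tests are upper bounds in that sense.
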