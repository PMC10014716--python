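# Methods

This note documents the models implemented in `riskbn`, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot establish.

## 1. The classifier

### Structure learning

For discrete predictors X₁…X_p and binary outcome Y, the tree-augmented
naïve Bayes network gives every predictor the class as a parent and at most
one augmenting parent among the other predictors. Augmenting edges are
chosen in three steps:

1. **Weights.** Empirical conditional mutual information
   I(Xᵢ; Xⱼ | Y) = Σ p̂(xᵢ,xⱼ,y) ln [ p̂(xᵢ,xⱼ|y) / (p̂(xᵢ|y) p̂(xⱼ|y)) ],
   computed in nats (reported in bits in user output).
2. **Pruning.** A pair enters the candidate set only if the G² test
   G² = 2 Σ O ln(O/E), conditioned on Y, rejects independence at α = 0.01.
   Degrees of freedom sum (levelsᵢ−1)(levelsⱼ−1) over non-empty strata;
   zero-count cells contribute nothing. Conditioning sets are capped at 5
   variables (the analysis' pre-specified maximum); by default only Y is
   conditioned on.
3. **Forest.** Kruskal's algorithm on the surviving edges, weights
   descending, ties broken lexicographically by (sorted) variable-name
   pair so that results never depend on column order. Each tree is rooted
   at its member with the highest I(X; Y) (lexicographic tie-break) and
   directed away from the root. If every edge is pruned the model *is*
   naïve Bayes — a legitimate outcome, not an error.

### Parameters and inference

CPT entries are (count + a) / (total + a·levels) with pseudo-count a = 1
(configurable); every entry is strictly positive, so sparse strata —
common at 5 bins × 5 parent bins × 2 classes on n ≈ 900 — never produce
zero posteriors. Prediction accumulates log-factors and normalises over
the two classes; a brute-force joint-table enumeration oracle in the test
suite confirms exactness to 1e−12.

### Degenerate inputs

Single-predictor models have an empty forest. Constant columns are
dropped (with a warning) at discretization. Levels absent from a training
fold but present in the schema receive the smoothed prior mass. Unmapped
categorical levels raise a validation error naming the column.

## 2. Discretization

The analysis is fully discrete. Continuous scores use equal-frequency
binning, k = 5 by default: cut points at the training-sample quantiles,
duplicate quantiles merged (fewer bins allowed — a column that is 90%
zeros typically ends with 2–3 bins). Frequency binning is robust to the
strong skew of psychometric totals. The scheme is an object fit on one
sample and applied to another: out-of-range values fall into the first or
last bin, which is exactly what cross-country transfer needs. Age keeps
its six survey bands; education and income are ordinal with schema-fixed
levels identical in both countries, so cross-country mapping is by
ordinal position. Inside cross-validation the discretizer is refit on
every training fold; the final model's scheme is fit on the full training
country and frozen for out-of-country testing.

## 3. Predictor selection

Two noise (shadow) variables are appended once per dataset, before any
cross-validation: a continuous N(mean, SD) column matched to the sample's
PHQ-9 total and discretized by the same k-bin rule, and a binary column
with the sample's male rate. Outcome-stratified ten-fold CV (17%
prevalence makes unstratified folds unstable) trains one TAN per fold on
all candidates. Importance of a variable is the drop in Nagelkerke R²
when its column is permuted, averaged over 10 seeded permutations,
floored at 0 — permutation streams are keyed by variable name, so
retention is invariant to column order. A candidate beats noise in a fold
iff its raw importance strictly exceeds both noise importances (ties count
against the candidate); variables beating noise in >5 folds are retained.

**Where importance is scored.** On each fold's held-out tenth, with the
training fold's bins applied. This is what gives the rule its type-I
control: under a global null the fold model is no better than the outcome
base rate out of fold, its held-out R² floors at exactly 0, every
importance ties at 0, and nobody beats anybody. (Scoring on the training
part instead makes candidate and noise importances exchangeable —
everything earns a positive overfit contribution — and the per-variable
false-retention rate rises to ~1/3; measured, not hypothetical.) With the
held-out scheme the measured per-variable retention rate over 200 null
datasets is ≤ 1.5%.

**Posterior recalibration for scoring.** Product-form posteriors with ~20
predictors are strongly over-dispersed out of fold (measured Platt slope
≈ 0.45 on pooled out-of-fold predictions at n ≈ 1,000). The selection
therefore runs two passes: fold models are fitted first and their pooled
out-of-fold posteriors fit a single logistic slope/intercept (Platt), and
per-fold importances are then scored on recalibrated posteriors with
probabilities clipped to [0.01, 0.99]. The two shared parameters are
identical for candidates and noise columns, so the beats-noise comparison
stays symmetric; ranking (hence AUC) is untouched. Headline R² values in
evaluation reports are unclipped and unrecalibrated.

The final network is trained on the full country sample restricted to the
retained variables (noise excluded). An empty retained set raises an
explicit no-signal error. No hyperparameter is tuned anywhere; CV is used
solely for variable selection.

## 4. Evaluation

* **AUC** in the Mann–Whitney rank-sum form (ties counted ½), checked
  against an independent implementation to 1e−12 in tests.
* **PPV/NPV** at posterior ≥ 0.5 by default (the threshold is
  configurable and reported with the prevalence, since predictive values
  are prevalence-dependent); an empty predicted class yields NaN with a
  warning, not a crash.
* **Nagelkerke R²**: R²_CS = 1 − exp((2/n)(ℓ₀ − ℓ₁)) over its maximum
  1 − exp((2/n)ℓ₀), with ℓ₀ the log-likelihood of the evaluated sample's
  base rate. A model beaten by the null reports 0 with a warning.
* **Shrinkage** = AUC(within) − AUC(out), after the test country is
  mapped through the training country's frozen discretizer.
* **Directions.** P̂(Y=1 | bin) is the mean model posterior within each
  bin of a variable (empirically marginalising the others). Ordered
  variables with a positive first-to-last difference and a weakly
  monotone trend (backward steps up to 15% of the total trend tolerated —
  bin means on ~200 rows are noisy) are risk factors; negative mirrored
  for protective; unordered categoricals with >2 levels are non-monotone
  by definition. The magnitude is always reported so flat trends can be
  discounted by the reader.
* Importance is reported both as raw ΔR² and as a share normalised to
  100% across model variables (the published figures' normalised indices
  correspond to the latter).

## 5. The synthetic survey generator

The generator stands in for survey microdata that are not publicly
deposited. It emulates the two samples' *published summary statistics*,
not their raw joint distribution.

* **Latent traits.** 13 standard-normal traits (depression, anxiety,
  helplessness, insomnia, loneliness, self-efficacy, resilience, four
  QOL domains, exercise, household size) under a Gaussian copula.
  Default correlations: 0.2 within the risk and protective blocks,
  depression–anxiety 0.7, depression–loneliness 0.5, depression ×
  protective −0.4, other risk × protective −0.2, household independent
  (minimum eigenvalue ≈ 0.12). The published analysis reports no
  correlation matrix; these are package defaults exposed in the config.
* **Scale scores.** Each bounded sum score is the trait quantile-mapped
  through a discrete exponential family p(k) ∝ exp(a·t + b·t²) solved so
  the distribution's mean and SD equal the published values exactly.
  For b < 0 this is a discretized truncated normal; the extension to
  b ≥ 0 is required because some published SDs (e.g. 6.99 at mean 8.38 on
  0–24) exceed the discretized-normal maximum. Measurement reliability
  0.85 per scale (observed-score latent = √rel·trait + √(1−rel)·noise)
  reflects that real questionnaires measure their construct imperfectly.
* **Suicidal-ideation item.** P(item 9 ≥ 1) = logistic(β₀ + βᵀz) on the
  standardized traits; severity 1/2/3 given endorsement follows a fixed
  (0.7, 0.2, 0.1) split (the analysis binarises the item, so the split
  only perturbs the PHQ-9 total mildly). Default β: depression 1.0
  (re-set by calibration), loneliness 0.6, anxiety 0.5, small effects
  (|β| ≤ 0.15) for the remaining traits, signed risk/protective — a
  trio-dominant profile mirroring the importance pattern of the published
  networks.
* **Calibration.** Three quantities are matched by alternating bisection
  on a fixed 200,000-draw Monte-Carlo sample (tolerance 0.003, common
  random numbers): β₀ → marginal SI prevalence; the depression
  coefficient → SI prevalence among PHQ-9 ≥ 10; and an exponential tilt
  of the PHQ-8 marginal at the cutoff → the depression rate implied by
  total probability ((0.173−0.073)/(0.550−0.073) ≈ 0.2096 for Austria,
  ≈ 0.4111 for the UK). The tilt is the third natural parameter of the
  same discrete family; mean and SD are re-solved exactly at every tilt
  value. The SI prevalence among the *non*-depressed is never fitted — it
  emerges from total probability and lands within Monte-Carlo error of
  the published 7.3% / 8.8%. Item 9 contributes to its own conditioning
  total (endorsement adds 1–3 points toward PHQ-9 ≥ 10), which is why
  calibration is simulation-based rather than closed-form.
* **Demographics** are drawn independently from the published category
  frequencies, except that in the UK config age shifts the helplessness
  latent (+0.5 young → −0.5 old, re-standardised), so an age effect is
  exercisable through the pipeline as in the published UK network.

### What the generator does *not* emulate

Real item-level response styles, differential item functioning, quota
sampling, missingness (complete cases only, as in the survey after
exclusions), temporal/lockdown dynamics, and any dependence structure
beyond a one-factor-per-scale Gaussian copula. Consequently, passing
tests show that the *pipeline* behaves correctly under realistic
conditions — calibrated prevalences, correlated predictors, paper-scale
samples — not that the published edge sets or importance percentages are
recovered; those depend on the unavailable raw data. Observed end-to-end
behaviour under the default conditions (within-sample AUC ≈ 0.87–0.95,
R² ≈ 0.4–0.65, shrinkage ≈ 0.01–0.10, retained sets of 4–15 variables
always containing the depression/anxiety/loneliness trio) brackets the
published figures (AUC 0.84/0.93 within, 0.80/0.79 out; R² 47.1%/49.5%;
10/12 retained variables).

## 6. Problem sizes and seeds

Simulation-based tests use the published sample sizes (n = 1,005 / 1,006)
with 20 generator seeds where behaviour across samples is asserted;
structure recovery uses 50 seeds at n = 5,000; the selection null
calibration uses 200 datasets of n = 250 with 6 candidates plus the two
noise columns. Calibration is deterministic (fixed seed 2020, 200,000
draws) and every stochastic step — generation, folds, permutations,
noise — takes an explicit seed; identical configs reproduce outputs
byte-for-byte, including CSV and JSON artifacts.

## 7. Known limitations

* Importance is permutation-based ΔR²; correlated predictors share
  credit, so a variable's low importance does not imply no association.
* The held-out R² gate makes fold-level retention conservative in small
  folds; with ~100-row folds, weakly informative variables (true |β|
  ≲ 0.1 here) are often not retained — consistent with the selection's
  purpose of keeping only reliable predictors.
* PPV/NPV at threshold 0.5 are reported for comparability, but with 17%
  prevalence the predicted-positive class can be small; consumers should
  reinterpret against the reported prevalence.
* The G² pruning uses only Y-conditioning by default; conditioning sets
  up to 5 are supported but not exercised by the default pipeline.
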