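# riskbn

Bayesian-network analysis of psychosocial risk and protective factors for
suicidal ideation, built around a from-scratch **Tree-Augmented Naïve Bayes
(TAN)** classifier with noise-variable (shadow-feature) predictor selection
and a cross-country transfer harness — plus a calibrated synthetic survey
generator that emulates two general-population pandemic-era samples
(Austria, *n* = 1,005; UK, *n* = 1,006).

## Who this is for

Researchers in psychiatric epidemiology and prevention science who want to
model how depression, anxiety, loneliness, stress, sleep, resilience,
quality of life and demographics *jointly* predict suicidal ideation
(PHQ-9 item 9 endorsed at any frequency), rather than testing main effects
one at a time — and to check whether the discovered predictors generalise
to a sample from a different country.

## The model

TAN extends naïve Bayes by allowing each predictor one additional parent
besides the outcome *Y*, so the network captures two-way interactions:

    P(y | x) ∝ P(y) · ∏ᵢ P(xᵢ | y, pa(xᵢ))

* **Structure.** Augmenting edges maximise conditional mutual information
  I(Xᵢ; Xⱼ | Y) (Chow–Liu applied class-conditionally) over a maximum-weight
  spanning forest; candidate edges must first reject independence in a
  likelihood-ratio G² test (α = 0.01, conditioning sets capped at 5).
* **Parameters.** Conditional probability tables with additive ("Bayes
  adjustment") smoothing, pseudo-count 1 — no zero cells in sparse strata.
* **Predictor selection.** Two noise variables — a continuous one matched
  to the PHQ-9 total's mean/SD and a binary one matched to the male base
  rate, both independent of the outcome — join all candidates in a ten-fold
  cross-validation. Per fold, permutation importance (drop in held-out
  Nagelkerke R², 10 permutations) ranks every variable; a candidate is
  retained only if it beats **both** noise variables in more than half
  (>5) of the ten folds.
* **Evaluation.** Mann–Whitney AUC, PPV/NPV at a posterior threshold of
  0.5, Nagelkerke R², and prediction shrinkage (within-sample AUC minus
  out-of-country AUC) after mapping the second country through the
  training country's frozen discretization; each retained predictor is
  annotated risk/protective from the direction of its bin-wise posterior
  trend.

Because the original survey microdata are not publicly deposited, the
package ships a seeded generator whose marginals (all scale means/SDs and
demographic frequencies), suicidal-ideation prevalences (17.3% / 31.7%
overall; 55.0% / 64.5% among PHQ-9 ≥ 10) and depression rates are
calibrated to the published sample-characteristics table via a Gaussian
copula over latent traits. See `docs/methods.md` for the model and its
limits.

## Worked example

```python
from riskbn import synthdata, pipeline

cfg_at = synthdata.calibrated_config("austria")   # ~2 s, seeded
cfg_uk = synthdata.calibrated_config("uk")
austria = synthdata.generate_survey(cfg_at, seed=11)
uk = synthdata.generate_survey(cfg_uk, seed=12)

analysis, report = pipeline.cross_country_study(austria, uk, seed=5)
print(analysis.selection.retained)
print(f"AUC within={report.auc_within:.3f} out={report.auc_out:.3f} "
      f"shrinkage={report.shrinkage:.3f} R2={report.nagelkerke:.3f}")
```

prints (exactly, for these seeds):

```
['exercise_days', 'phq8', 'gad7', 'pss_selfefficacy', 'loneliness',
 'cdrisc', 'whoqol_physical', 'whoqol_psychological',
 'whoqol_relationships', 'whoqol_environment']
AUC within=0.923 out=0.864 shrinkage=0.059 R2=0.554
```

Ten predictors survive the noise threshold: depression severity (PHQ-8),
anxiety (GAD-7) and loneliness rank highest (55.3%, 10.2% and 6.8% of the
normalised importance), with self-efficacy, resilience, exercise and
quality-of-life domains acting as protective factors. The Austria-trained
network transfers to the UK sample with a shrinkage of 0.059 — the same
qualitative picture as the published cross-country analysis (AUC ≈ 0.84
within / 0.80 out, shrinkage 0.04). `analysis.model.results.summary()`
shows the fitted network; `riskbn.export.to_dot(...)` writes the DAG with
risk factors in red and protective factors in green.

The same pipeline is scriptable:

```bash
riskbn simulate --country austria --seed 7 --out out/sim
riskbn simulate --country uk --seed 8 --out out/sim
riskbn crosscountry --train-csv out/sim/austria.csv \
    --test-csv out/sim/uk.csv --seed 5 --out out/run
```

which writes `report.json`, `metrics.csv`, the model JSON and DOT/GraphML
graphs, plus a manifest that reproduces the run byte-for-byte.

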