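# missig — is ICU laboratory missingness informative?

`missig` is a pipeline for studying *informative missingness* in intensive
care laboratory data. In an ICU, a lab test is absent from a patient-day
record because a clinician decided not to order it — the data are missing
not at random (MNAR), and the absence itself carries information about the
patient's state. The package is aimed at biostatisticians and clinical
machine-learning researchers who want to quantify that information.

## The core idea

For a patients × tests value matrix `X` for one ICU day (36 common lab
tests, explicit absent entries), define the **missingness-indicator
matrix** `I` with

```
I[i, t] = 1  if test t is absent from patient i's record,  else 0
```

impute the absent values with a donor-based method (hot deck or predictive
mean matching), and form the **augmented matrix** `[X_imputed | I]`. The
pipeline then measures, on binary mortality outcomes:

- **Exploration** — per-test missingness rates; the phi-correlation matrix
  of the indicators, whose connected components at φ ≥ 0.95 recover the
  panels of tests that are ordered together; the Spearman correlation ρ
  between a patient's missing-test count and a severity-of-illness score
  (negative under MNAR: sicker patients get more tests).
- **Feature selection** — a filter ensemble (|logistic β|, ReliefF,
  information gain; min–max normalized and averaged) ranking every value
  and indicator column, plus a cross-validated L1 logistic path reporting
  the fraction of indicators among the features selected at λ_min and at
  the one-standard-error penalty λ_1SE.
- **Prediction** — repeated stratified 10-fold CV (shared folds = paired
  design) of logistic regression, a pruned decision tree, and a random
  forest over five input sets (indicators only, imputed values only,
  augmented, severity score only, severity score + indicators), with
  AUROC percentile intervals and paired fold-wise AUROC deltas such as
  `AUROC(augmented) − AUROC(imputed)`.

Because the motivating clinical database is access-restricted, the package
includes a first-class synthetic cohort generator: latent severity
`s ~ N(0,1)`, logistic outcomes on `s`, panel ordering with log-odds
`γ(panel, day) + δ·s` (so `δ > 0` makes missingness severity-linked; a
switch produces the matched MCAR null cohort), independent within-panel
dropout, and Gaussian test values loaded on `s`. See `docs/methods.md` for
the full mechanism and every default.

## Worked example

```python
from missig import (
    SimulationConfig, generate_cohort, build_indicator_matrix,
    build_augmented_matrix, pmm_impute, ImputationSpec,
    spearman_missing_vs_severity, phi_matrix, find_groups,
    ensemble_rank, compare_input_sets, ModelSpec, CVScheme,
)

cohort = generate_cohort(sim=SimulationConfig(n_patients=2000), seed=1)
day1 = cohort.day(1)

ind = build_indicator_matrix(day1.values)
rho, p = spearman_missing_vs_severity(ind, day1.severity_score)
groups = find_groups(phi_matrix(ind), threshold=0.95)
print(f"spearman rho = {rho:.3f}, phi groups = {len(groups)}")

imp = pmm_impute(day1.values, ImputationSpec(rng_seed=1))
aug = build_augmented_matrix(imp, ind)
table = ensemble_rank(aug, day1.outcomes["in_hospital"])
print(f"indicators in top 18: {table.indicator_fraction_top(18):.0%}")

comp = compare_input_sets(
    day1, "in_hospital", models=[ModelSpec("logistic")],
    cv=CVScheme(n_folds=10, n_repeats=2), seed=1,
)
print(comp.summary[["input_set", "mean"]].round(3))
print(comp.deltas[["pair", "mean", "lo", "hi"]].round(3))
```

Output:

```
spearman rho = -0.585, phi groups = 7
indicators in top 18: 100%
                  input_set   mean
0           indicators_only  0.741
1              imputed_only  0.660
2                 augmented  0.733
3             severity_only  0.758
4  severity_plus_indicators  0.771
                                     pair   mean     lo     hi
0                  augmented-imputed_only  0.072  0.003  0.158
1  severity_plus_indicators-severity_only  0.013 -0.038  0.062
```

Read: missingness is strongly severity-linked (ρ = −0.59), the seven
ordering panels reappear as phi blocks, indicators dominate the ensemble
ranking, indicators alone predict mortality well above chance
(AUROC 0.74), and adding them to the imputed values raises AUROC by 0.072
with a percentile interval excluding zero. On the matched MCAR null cohort
(`mcar_variant`) all of these effects vanish.

The same analysis runs from the shell:

```
missig run --seed 1 --outdir out/            # full pipeline, all days/outcomes
missig run --config my.yaml --with-null ...  # plus the MCAR twin
missig simulate | impute | explore | select | predict   # individual stages
```

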