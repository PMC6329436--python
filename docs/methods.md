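# Methods

## The question and the representation

In intensive care, laboratory tests are ordered when a clinician judges them
necessary. The *absence* of a test from a patient-day record is therefore not
noise: it reflects the patient's state and the care process, i.e. the data are
missing not at random (MNAR). This package operationalizes that idea.

Given a patients × tests value matrix for one ICU day with explicit absent
entries, three derived matrices are built:

- the **auxiliary (indicator) matrix** `I`, with `I[i,t] = 1` if test `t` is
  absent from patient `i`'s day record and `0` if present (columns named
  `I-<test>`);
- an **imputed matrix** with every absent cell filled by a donor-based method
  (hot deck or predictive mean matching);
- the **augmented matrix** — imputed values joined column-wise with the
  indicators — so a model sees both the measured (or imputed) values and the
  presence pattern, and can distinguish imputed cells from measured ones.

The indicator coding is fixed at 1 = absent. All downstream sign
interpretations assume this coding.

The analysis then asks three questions: (i) is missingness linked to
severity of illness (Spearman correlation between per-patient missing-test
count and a severity score; phi association between each indicator and
mortality)? (ii) do indicators rank as informative predictors (a filter
ensemble and an L1 path)? (iii) do indicators improve mortality prediction
(paired cross-validated AUROC over five input sets)?

## The synthetic cohort generator

The real data behind this design is a credentialed-access clinical database,
so the package ships a generator whose *structure* matches a daily ICU lab
extract; all tests run against it.

Mechanism, per patient `i`:

- latent severity `s_i ~ N(0, 1)`;
- outcomes `y ~ Bernoulli(expit(alpha + beta * s_i))` for in-hospital and
  30-day mortality, `beta = 1.5`, with `alpha` solved by Gauss–Hermite
  quadrature so marginal prevalences are 0.11 (in-hospital) and 0.15
  (30-day) — the day-1 rates of the cohort being emulated;
- per ordering panel `g` and day `d`, the panel is ordered with probability
  `expit(gamma(g,d) + delta_g * s_i)`. `delta_g >= 0` is the MNAR link
  (default 1 for every panel; a dict allows per-panel overrides; 0 everywhere
  is MCAR). `gamma(g,d)` is solved by quadrature so the *marginal* ordering
  probability hits a per-panel day-1 target, shifted by −0.5 log-odds per
  day (ordering grows more selective on days 2 and 3);
- a test in an ordered panel is independently dropped with probability
  `eps` (default 0.01);
- present values are `mu_t + lambda_t * s_i + sigma_t * e`, `e ~ N(0,1)`,
  defaults `mu = 0`, `lambda = 0.15`, `sigma = 1`;
- the emitted severity score is `s_i + 0.75 * N(0,1)`, a deliberately noisy
  stand-in for a clinical severity-of-illness index such as SAPS-II;
- patients violating the eligibility rule (no data point on some day) are
  regenerated when `n <= 1000` (small fixtures keep exact n) and dropped,
  with a count in the ground-truth log, otherwise.

The 36 tests and the seven multi-test panels (differential white count,
red-cell indices, blood gas, liver enzymes, BUN/Cr, Cl/HCO3, PT/PTT) follow
the standard co-ordering structure of ICU labs; the remaining tests are
singleton panels, since no co-ordering is documented for them.

### Calibration choices, and why

Two tensions shaped the default parameters; both are deliberate and fixed.

**Panel missingness floors.** With independent within-panel dropout, the phi
correlation between two same-panel indicators is
`(1-eps)(1-p) / (1 - p(1-eps))` where `p` is the ordering probability. As
`p -> 1` this tends to 0: for a panel ordered for ~98% of patients, even
`eps = 0.01` destroys the phi block. Real co-ordered panels can sit at ~1%
missingness only because their residual dropout is essentially zero. Since
the package's panel-recovery check requires the phi blocks to survive
`eps = 0.01` at threshold 0.95, every multi-test panel defaults to >= 25%
day-1 missingness (`p <= 0.75`); the ~1–3% end of the missingness spectrum is
carried by singleton panels (Na, K, glucose, CBC counts). Day-1 targets:
liver 0.70, differential count 0.65, lactate 0.75, blood gas and pH 0.45,
coagulation 0.35, red-cell indices / renal / anions / phosphate 0.25,
magnesium 0.12, calcium 0.10, common chemistries 0.015–0.03. By day 3 the
most selective tests exceed 85% missing.

**Value/severity-score informativeness.** Indicators, measured values, and
the severity score all proxy the same latent severity. If values are nearly
noiseless proxies, indicators cannot add predictive signal and the central
phenomenon — an AUROC gain from augmentation — vanishes by construction. The
defaults (`lambda = 0.15` against unit value noise; severity-score noise SD
0.75) place the input sets in the qualitative order reported for real ICU
data: indicator-only models clearly beat chance, imputed values alone do a
bit worse than indicators under the default link strength, augmentation adds
roughly +0.05 AUROC over imputed values alone, and indicators also improve
the severity-score baseline. These are mechanism parameters of the emulation,
not fitted quantities.

### What the generator does not emulate

Gaussian values with no units or reference ranges (cosmetic; no attempt to
match lab distributions); a fixed cohort across the three days (no discharge
or death attrition, so later-day prevalences do not rise as they would in a
real cohort); no within-day time stamps; outcomes identical across days by
construction; a single latent severity collapsing comorbidity and physiology
scores into one scalar. Consequently, passing tests show the *methods*
behave correctly under a controlled MNAR mechanism — not that real ICU
missingness carries this much signal.

## Imputation

Both methods are donor-based: an imputed cell always takes an observed value
of the same column from some donor patient, never a synthetic number.

- **Hot deck**: nearest donor under root-mean-square distance over the
  standardized columns both patients have observed; ties broken by a seeded
  uniform draw; a recipient sharing no observed column with any donor falls
  back to a seeded random observed donor (logged).
- **PMM** (k = 5 donors, a widely used convention): per target column, a
  linear predictor on the other columns is fitted by least squares on the
  rows observed for that column (absent predictors pre-filled with column
  means for the design only; rank-deficient designs fall back to the
  minimum-norm solution, logged); each absent cell takes the observed value
  of one of the k donors with the closest predicted mean, chosen by a seeded
  draw.

Randomness is keyed per column and consumed in stable patient-id order, so
imputation is invariant to row permutation. Each day is imputed
independently, and one completed matrix is produced per method (single, not
multiple, imputation — matching the single-completed-matrix design the
pipeline evaluates). Both methods accept a separate training frame so
cross-validation can fit the donor pool and regression on training folds
only.

## Feature scoring and selection

Three filter scores per feature of the augmented matrix:

- `lr_beta`: absolute standardized coefficients of one multivariable
  logistic model fitted by IRLS with a fixed ridge stabilizer (1e-3 on the
  standardized scale; the multivariable-with-ridge choice is declared —
  a univariable variant would ignore collinearity entirely). Constant
  columns score 0.
- `relief`: ReliefF for binary outcomes, k = 10 neighbors, Manhattan
  distance on [0,1]-scaled features, every instance used.
- `infgain`: outcome-entropy reduction in bits, numeric features cut into
  10 equal-frequency bins (duplicate edges merged); features with <= 2
  levels used as-is.

Scores are min–max normalized per method and averaged (score-mean is the
default aggregation because it preserves margin information; rank-mean is
implemented and selectable; the table records which was used). A degenerate
(all-equal) method contributes 0.5 to every feature and is flagged. Final
ranks break ties lexicographically by feature name for cross-platform
determinism. The top-18 view and the fraction of indicators in it are the
published-table analogues.

The embedded route is an L1-penalized logistic path: 30 penalties log-spaced
from just above the all-zero threshold `max_j |x_j'(y - ybar)|/n` down by
1e-4, solved by liblinear (fixed `random_state`, tol 1e-4, the
lambda-to-C mapping `C = 1/(n*lambda)`). Repeated stratified CV scores each
penalty by binomial deviance (AUROC reported alongside); `lambda_min`
minimizes mean deviance and `lambda_1se` is the largest penalty within one
standard error of that minimum. Selection criterion is deviance, not AUROC,
because the one-standard-error rule is defined on an error curve.

## Prediction and evaluation

AUROC is computed in the Mann–Whitney form (ties credited 0.5). Evaluation
is repeated stratified k-fold CV (default 10 × 20, giving 200 fold values)
with one shared fold assignment across all input sets and models, so input
sets can be compared as paired fold-wise deltas. Intervals are 2.5–97.5
percentile intervals over the fold AUROCs; fold values are not independent,
which the output metadata records.

Models: the same ridge-IRLS logistic regression used by the filter; a
decision tree whose cost-complexity pruning strength is tuned by inner
3-fold CV over the grid {0, 0.0025, 0.005, 0.01, 0.02} with ties broken
toward the smaller tree; a random forest with 500 trees (100 in the
scaled-down null-calibration test) and square-root feature subsampling.
Standardization, imputation models, and tree tuning are all fitted inside
training folds; an `impute_once` switch reproduces the simpler
impute-up-front protocol.

Input sets: `indicators_only`, `imputed_only`, `augmented`,
`severity_only` (the severity score as a single-column clinical baseline),
`severity_plus_indicators`.

## Numerical and degenerate-input choices

- Phi on a constant vector is undefined and reported as flagged NaN, never
  coerced to 0 (a silent zero would distort rankings).
- Phi groups are connected components of the thresholded phi graph, not
  cliques — the weakest rule consistent with "groups of highly correlated
  indicators"; the no-dropout limit pins the behavior exactly.
- Spearman p-values use the large-sample t approximation with midranks.
- IRLS caps at 100 iterations (step tolerance 1e-8) and fails loudly with
  the stabilizer value; weights are floored at 1e-10 and linear predictors
  clipped at ±30.
- Hot-deck distance ties use a 1e-9 relative tolerance.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; imputation tie-breaks are keyed to patient
  ids, not row positions.

## Problem sizes in the shipped tests

The full default protocol (n in the tens of thousands, 10 × 20 CV, 500-tree
forests) is a headline-run configuration. The shipped test-suite and the
reproduction script use scaled-down sizes chosen as adequate for their
statistical purpose: cohorts of 2000 (5000 where a tight null band is
needed), CV with 1–2 repeats, 100-tree forests for null calibration, and a
200-patient pipeline for the byte-reproducibility check. The MCAR
null-calibration checks aggregate statistics over a fixed set of five seeds,
because single-seed maxima over 36 indicators are not expected to meet the
stated bands at n = 2000.

## Known limitations

- Indicator-only AUROC and the severity correlation are stronger in the
  simulation than in published real-data analyses: a single global severity
  link (`delta = 1` for every panel) is a cleaner mechanism than real
  ordering behavior.
- Connected-component grouping can chain distinct panels through a single
  borderline pair at looser thresholds; at 0.95 with the default mechanism
  this does not occur.
- The L1 path's liblinear solver penalizes the intercept; intercept scaling
  (10.0) makes the distortion negligible at these prevalences but the path
  is not glmnet-exact.
- `lambda_1se >= lambda_min` and the sparsity ordering of the two selected
  sets hold on every tested configuration but are properties of the fitted
  path, not enforced constraints.
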