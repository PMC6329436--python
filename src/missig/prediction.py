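"""Repeated cross-validated AUROC comparison across model input sets.

Three model families — ridge-stabilized logistic regression (IRLS fit),
a cost-complexity-pruned decision tree (pruning strength tuned by inner CV
over a grid from 0 to 0.02), and a random forest — are evaluated over five
input sets:

* ``indicators_only`` — the binary missingness indicators alone;
* ``imputed_only`` — imputed laboratory values alone;
* ``augmented`` — values plus indicators;
* ``severity_only`` — the severity score alone (the clinical-score baseline);
* ``severity_plus_indicators`` — severity score plus indicators.

Fold assignments are shared across input sets and models (a paired design),
so AUROC deltas between input sets can be computed fold by fold.  Every
data-dependent transformation — standardization, imputation-model fitting,
tree pruning — is learned inside the training folds only; a compatibility
switch (`impute_once`) instead imputes the whole matrix up front, matching
the simpler protocol of imputing before cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .feature_selection import fit_logistic_irls
from .imputation import ImputationSpec, impute
from .lasso import CVScheme
from .representation import build_augmented_matrix, build_indicator_matrix
from .simulate import CohortDay

__all__ = [
    "auroc",
    "ModelSpec",
    "tune_tree_cp",
    "repeated_cv",
    "compare_input_sets",
    "AUROCComparison",
    "INPUT_SETS",
    "DEFAULT_CP_GRID",
]

INPUT_SETS = (
    "indicators_only",
    "imputed_only",
    "augmented",
    "severity_only",
    "severity_plus_indicators",
)

#: Cost-complexity grid; endpoints fixed at 0 (full tree) and 0.02.
DEFAULT_CP_GRID = (0.0, 0.0025, 0.005, 0.01, 0.02)


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(random positive scores above random negative),
    ties credited 0.5."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).astype(int).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family with its fixed, documented settings."""

    family: str  # logistic | decision_tree | random_forest
    cp_grid: tuple[float, ...] = DEFAULT_CP_GRID
    inner_folds: int = 3
    rf_trees: int = 500
    rf_max_features: str = "sqrt"

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "decision_tree", "random_forest"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "decision_tree":
            if self.cp_grid[0] != 0.0 or self.cp_grid[-1] != 0.02:
                raise ValueError("cp_grid endpoints must be exactly 0 and 0.02")


def tune_tree_cp(
    X: np.ndarray,
    y: np.ndarray,
    cp_grid=DEFAULT_CP_GRID,
    inner_folds: int = 3,
    seed: int = 0,
) -> float:
    """Pick the pruning strength by inner cross-validated AUROC.

    The same inner folds evaluate every grid value; ties break toward the
    larger CP (the smaller tree).
    """
    if len(cp_grid) == 1:
        return float(cp_grid[0])
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed % (2**31))
    folds = list(skf.split(X, y))
    best_cp, best_score = None, -np.inf
    for cp in sorted(cp_grid):  # ascending: '>=' keeps the largest tied CP
        scores = []
        for tr, te in folds:
            clf = DecisionTreeClassifier(ccp_alpha=cp, random_state=0)
            clf.fit(X[tr], y[tr])
            scores.append(auroc(clf.predict_proba(X[te])[:, 1], y[te]))
        mean = float(np.mean(scores))
        if mean >= best_score:
            best_cp, best_score = float(cp), mean
    return best_cp


def _fit_predict(
    spec: ModelSpec,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Fit one model on a training fold and score the held-out fold."""
    if spec.family == "logistic":
        mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        beta = fit_logistic_irls((X_tr - mu) / sd, y_tr.astype(float))
        eta = np.clip(beta[0] + ((X_te - mu) / sd) @ beta[1:], -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))
    if spec.family == "decision_tree":
        cp = tune_tree_cp(X_tr, y_tr, spec.cp_grid, spec.inner_folds, seed)
        clf = DecisionTreeClassifier(ccp_alpha=cp, random_state=seed % (2**31))
    else:
        clf = RandomForestClassifier(
            n_estimators=spec.rf_trees,
            max_features=spec.rf_max_features,
            random_state=seed % (2**31),
            n_jobs=1,
        )
    clf.fit(X_tr, y_tr)
    return clf.predict_proba(X_te)[:, 1]


def repeated_cv(
    model: ModelSpec,
    X: pd.DataFrame,
    y,
    cv: CVScheme | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Fold-level AUROCs over a repeated stratified CV of one feature matrix.

    Returns n_folds * n_repeats values in (repeat, fold) order.  Identical
    inputs and seed give an identical vector.
    """
    cv = cv or CVScheme()
    yv = np.asarray(y).astype(int).ravel()
    Xv = X.to_numpy(dtype=float)
    out = []
    for fi, (tr, te) in enumerate(cv.splitter(seed).split(Xv, yv)):
        if len(np.unique(yv[tr])) < 2 or len(np.unique(yv[te])) < 2:
            raise ValueError(f"fold {fi} lost a class; check stratification/prevalence")
        p = _fit_predict(model, Xv[tr], yv[tr], Xv[te], seed=seed * 1000 + fi)
        out.append(auroc(p, yv[te]))
    return np.asarray(out)


@dataclass
class AUROCComparison:
    """Fold-level AUROCs per (model, input set) plus paired deltas."""

    folds: pd.DataFrame  # long: model, input_set, repeat, fold, auroc
    summary: pd.DataFrame  # model, input_set, mean, lo, hi
    deltas: pd.DataFrame  # model, pair, mean, lo, hi
    meta: dict = field(default_factory=dict)

    def fold_aurocs(self, model: str, input_set: str) -> np.ndarray:
        sel = (self.folds["model"] == model) & (self.folds["input_set"] == input_set)
        return self.folds.loc[sel].sort_values(["repeat", "fold"])["auroc"].to_numpy()


def _percentile_interval(x: np.ndarray) -> tuple[float, float]:
    return float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5))


DELTA_PAIRS = (
    ("augmented", "imputed_only"),
    ("severity_plus_indicators", "severity_only"),
)


def compare_input_sets(
    day: CohortDay,
    outcome: str,
    models: list[ModelSpec],
    cv: CVScheme | None = None,
    seed: int = 0,
    input_sets: tuple[str, ...] = INPUT_SETS,
    imputation: ImputationSpec | None = None,
    impute_once: bool = False,
) -> AUROCComparison:
    """Paired AUROC comparison of the input sets on one cohort day.

    One set of fold assignments is drawn and reused for every input set and
    model.  Imputation is refit inside each training fold by default;
    `impute_once` imputes the full matrix up front instead.
    """
    cv = cv or CVScheme()
    imputation = imputation or ImputationSpec(method="pmm", rng_seed=seed)
    for s in input_sets:
        if s not in INPUT_SETS:
            raise ValueError(f"unknown input set {s!r}; choose from {INPUT_SETS}")

    raw = day.values
    y = day.outcomes[outcome].to_numpy().astype(int)
    indicators = build_indicator_matrix(raw)
    severity = day.severity_score.to_frame()

    folds = list(cv.splitter(seed).split(raw.to_numpy(), y))

    needs_imputation = bool({"imputed_only", "augmented"} & set(input_sets))
    global_imp = None
    if needs_imputation and impute_once:
        global_imp = impute(raw, imputation)

    records = []
    for fi, (tr, te) in enumerate(folds):
        rep, fold = divmod(fi, cv.n_folds)
        fold_feats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if "indicators_only" in input_sets:
            Z = indicators.to_numpy(dtype=float)
            fold_feats["indicators_only"] = (Z[tr], Z[te])
        if "severity_only" in input_sets:
            Z = severity.to_numpy(dtype=float)
            fold_feats["severity_only"] = (Z[tr], Z[te])
        if "severity_plus_indicators" in input_sets:
            Z = np.column_stack([severity.to_numpy(dtype=float), indicators.to_numpy(dtype=float)])
            fold_feats["severity_plus_indicators"] = (Z[tr], Z[te])
        if needs_imputation:
            if impute_once:
                imp = global_imp
            else:
                train_frame = raw.iloc[tr]
                imp_tr = impute(train_frame, imputation, train=train_frame)
                imp_te = impute(raw.iloc[te], imputation, train=train_frame)
                values = pd.concat([imp_tr.values, imp_te.values]).loc[raw.index]
                mask = pd.concat([imp_tr.imputed_mask, imp_te.imputed_mask]).loc[raw.index]
                imp = type(imp_tr)(values=values, imputed_mask=mask, method=imp_tr.method)
            if "imputed_only" in input_sets:
                Z = imp.values.to_numpy(dtype=float)
                fold_feats["imputed_only"] = (Z[tr], Z[te])
            if "augmented" in input_sets:
                Z = build_augmented_matrix(imp, indicators).to_numpy(dtype=float)
                fold_feats["augmented"] = (Z[tr], Z[te])
        for model in models:
            for iset in input_sets:
                X_tr, X_te = fold_feats[iset]
                p = _fit_predict(model, X_tr, y[tr], X_te, seed=seed * 1000 + fi)
                records.append(
                    {
                        "model": model.family,
                        "input_set": iset,
                        "repeat": rep,
                        "fold": fold,
                        "auroc": auroc(p, y[te]),
                    }
                )

    long = pd.DataFrame.from_records(records)
    summaries, deltas = [], []
    for model in models:
        by_set = {
            iset: long[
                (long["model"] == model.family) & (long["input_set"] == iset)
            ].sort_values(["repeat", "fold"])["auroc"].to_numpy()
            for iset in input_sets
        }
        for iset, vals in by_set.items():
            lo, hi = _percentile_interval(vals)
            summaries.append(
                {
                    "model": model.family,
                    "input_set": iset,
                    "mean": float(vals.mean()),
                    "lo": lo,
                    "hi": hi,
                }
            )
        for a, b in DELTA_PAIRS:
            if a in by_set and b in by_set:
                d = by_set[a] - by_set[b]
                lo, hi = _percentile_interval(d)
                deltas.append(
                    {
                        "model": model.family,
                        "pair": f"{a}-{b}",
                        "mean": float(d.mean()),
                        "lo": lo,
                        "hi": hi,
                    }
                )
    meta = {
        "outcome": outcome,
        "day": day.day,
        "seed": seed,
        "cv": {"n_folds": cv.n_folds, "n_repeats": cv.n_repeats},
        "imputation": imputation.method,
        "impute_once": impute_once,
        "interval": "percentile over fold AUROCs (folds are not independent)",
        "rf": {"trees": max(m.rf_trees for m in models) if models else None},
    }
    return AUROCComparison(
        folds=long,
        summary=pd.DataFrame(summaries),
        deltas=pd.DataFrame(deltas),
        meta=meta,
    )
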