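"""Embedded feature selection: cross-validated L1 logistic path.

The path is evaluated by repeated stratified k-fold cross-validation with
binomial deviance as the selection criterion (AUROC reported alongside).
Two operating points are extracted:

* ``lambda_min`` — the penalty minimizing mean CV deviance (the
  best-performing model);
* ``lambda_1se`` — the largest penalty whose mean deviance stays within one
  standard error of that minimum (the sparser "adjusted" model).

For each point the nonzero-coefficient feature set is refit on the full
data, and the fraction of selected features that are missingness indicators
is reported — the headline statistic of the informativeness analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold

from .schema import INDICATOR_PREFIX

__all__ = ["CVScheme", "LassoResult", "lasso_select"]

_COEF_TOL = 1e-8


@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified k-fold scheme."""

    n_folds: int = 10
    n_repeats: int = 20
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"cv.n_folds must be >= 2, got {self.n_folds}")
        if self.n_repeats < 1:
            raise ValueError(f"cv.n_repeats must be >= 1, got {self.n_repeats}")

    def splitter(self, seed: int) -> RepeatedStratifiedKFold:
        if not self.stratified:
            raise ValueError("only stratified CV is supported")
        return RepeatedStratifiedKFold(
            n_splits=self.n_folds, n_repeats=self.n_repeats, random_state=seed % (2**31)
        )


@dataclass
class LassoResult:
    """Cross-validated L1 path summary at lambda_min and lambda_1se."""

    lambda_grid: np.ndarray
    cv_deviance_mean: np.ndarray
    cv_deviance_se: np.ndarray
    cv_auroc_mean: np.ndarray
    cv_auroc_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    selected_min: list[str]
    selected_1se: list[str]
    indicator_fraction_min: float
    indicator_fraction_1se: float
    auroc_min: tuple[float, float]  # (mean, se) at lambda_min
    auroc_1se: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lambda_grid": self.lambda_grid.tolist(),
            "cv_deviance_mean": self.cv_deviance_mean.tolist(),
            "cv_deviance_se": self.cv_deviance_se.tolist(),
            "cv_auroc_mean": self.cv_auroc_mean.tolist(),
            "cv_auroc_se": self.cv_auroc_se.tolist(),
            "lambda_min": self.lambda_min,
            "lambda_1se": self.lambda_1se,
            "selected_min": self.selected_min,
            "selected_1se": self.selected_1se,
            "indicator_fraction_min": self.indicator_fraction_min,
            "indicator_fraction_1se": self.indicator_fraction_1se,
            "auroc_min": list(self.auroc_min),
            "auroc_1se": list(self.auroc_1se),
            "meta": self.meta,
        }


class LassoConvergenceError(RuntimeError):
    pass


def _deviance(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _auroc(scores: np.ndarray, y: np.ndarray) -> float:
    from .prediction import auroc

    return auroc(scores, y)


def _fit_path(Z: np.ndarray, y: np.ndarray, lambdas: np.ndarray) -> list[LogisticRegression]:
    """L1 logistic fits along the penalty grid on standardized features."""
    n = Z.shape[0]
    fits = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for gi, lam in enumerate(lambdas):
            clf = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / (n * lam),
                solver="liblinear",
                random_state=0,
                intercept_scaling=10.0,
                max_iter=4000,
                tol=1e-4,
            )
            clf.fit(Z, y)
            if clf.n_iter_.max() >= 4000:
                raise LassoConvergenceError(
                    f"L1 solver hit the iteration cap at grid position {gi} "
                    f"(lambda={lam:.3e})"
                )
            fits.append(clf)
    return fits


def lasso_select(
    X: pd.DataFrame,
    y,
    cv: CVScheme | None = None,
    seed: int = 0,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 1e-4,
) -> LassoResult:
    """Cross-validate an L1 logistic path on an augmented matrix.

    The grid is log-spaced from just above the smallest penalty that zeroes
    every coefficient (computed from the gradient at the null model) down by
    `lambda_min_ratio`.  Features are standardized internally; fold
    standardization uses training statistics only.
    """
    cv = cv or CVScheme()
    yv = np.asarray(y).astype(float).ravel()
    if len(np.unique(yv)) < 2:
        raise ValueError("outcome is constant")
    Xv = X.to_numpy(dtype=float)
    names = list(X.columns)
    n = len(yv)

    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Zfull = (Xv - mu) / sd
    lam_max = np.abs(Zfull.T @ (yv - yv.mean())).max() / n
    lambdas = np.geomspace(lam_max * 1.01, lam_max * lambda_min_ratio, n_lambdas)

    folds = list(cv.splitter(seed).split(Xv, yv))
    dev = np.empty((len(folds), n_lambdas))
    auc = np.empty((len(folds), n_lambdas))
    for fi, (tr, te) in enumerate(folds):
        m, s = Xv[tr].mean(axis=0), Xv[tr].std(axis=0)
        s = np.where(s == 0, 1.0, s)
        Ztr, Zte = (Xv[tr] - m) / s, (Xv[te] - m) / s
        for gi, clf in enumerate(_fit_path(Ztr, yv[tr], lambdas)):
            p = clf.predict_proba(Zte)[:, 1]
            dev[fi, gi] = _deviance(p, yv[te])
            auc[fi, gi] = _auroc(p, yv[te])

    nf = len(folds)
    dev_mean, dev_se = dev.mean(axis=0), dev.std(axis=0, ddof=1) / np.sqrt(nf)
    auc_mean, auc_se = auc.mean(axis=0), auc.std(axis=0, ddof=1) / np.sqrt(nf)

    i_min = int(np.argmin(dev_mean))
    cutoff = dev_mean[i_min] + dev_se[i_min]
    i_1se = int(np.flatnonzero(dev_mean <= cutoff)[0])  # grid is decreasing in lambda
    lam_min, lam_1se = float(lambdas[i_min]), float(lambdas[i_1se])

    full_fits = _fit_path(Zfull, yv, lambdas)

    def selected(i: int) -> list[str]:
        w = full_fits[i].coef_.ravel()
        return [names[j] for j in np.flatnonzero(np.abs(w) > _COEF_TOL)]

    sel_min, sel_1se = selected(i_min), selected(i_1se)

    def ind_frac(sel: list[str]) -> float:
        if not sel:
            return float("nan")
        return sum(c.startswith(INDICATOR_PREFIX) for c in sel) / len(sel)

    return LassoResult(
        lambda_grid=lambdas,
        cv_deviance_mean=dev_mean,
        cv_deviance_se=dev_se,
        cv_auroc_mean=auc_mean,
        cv_auroc_se=auc_se,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        selected_min=sel_min,
        selected_1se=sel_1se,
        indicator_fraction_min=ind_frac(sel_min),
        indicator_fraction_1se=ind_frac(sel_1se),
        auroc_min=(float(auc_mean[i_min]), float(auc_se[i_min])),
        auroc_1se=(float(auc_mean[i_1se]), float(auc_se[i_1se])),
        meta={"seed": seed, "n_folds": cv.n_folds, "n_repeats": cv.n_repeats, "n": n},
    )
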