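"""Filter feature-selection ensemble: logistic betas, ReliefF, information gain.

Three filter scores are computed per feature of an augmented matrix, min-max
normalized to [0, 1], and averaged into one aggregate informativeness score;
features are then ranked (1 = most informative).  An `is_indicator` flag,
derived from the ``I-`` column prefix, lets downstream reports ask what share
of the top-ranked features are missingness indicators rather than measured
values.

Scorers:

* ``lr_beta_scores`` — absolute standardized coefficients of one
  multivariable logistic model, fitted by iteratively reweighted least
  squares with a small fixed ridge stabilizer.
* ``relief_scores`` — ReliefF for binary outcomes: per instance, the k
  nearest hits and k nearest misses (Manhattan distance on [0,1]-scaled
  features) push each feature's weight down/up by the mean feature
  difference.
* ``infgain_scores`` — reduction of outcome entropy (in bits) after
  partitioning on the feature, numeric features discretized into
  equal-frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import INDICATOR_PREFIX

__all__ = [
    "lr_beta_scores",
    "relief_scores",
    "infgain_scores",
    "ensemble_rank",
    "FeatureScoreTable",
    "IRLSError",
]

_RIDGE = 1e-3  # fixed stabilizer on the standardized-scale coefficients
_IRLS_MAX_ITER = 100
_IRLS_TOL = 1e-8


class IRLSError(RuntimeError):
    """IRLS failed to converge within the iteration cap."""


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean unit-variance columns; returns (Z, constant_mask)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd == 0
    sd = np.where(const, 1.0, sd)
    return (X - mu) / sd, const


def _check_y(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    return y


def fit_logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = _RIDGE,
    max_iter: int = _IRLS_MAX_ITER,
    tol: float = _IRLS_TOL,
) -> np.ndarray:
    """Ridge-stabilized logistic regression by IRLS.

    `X` must not include an intercept column (one is added, unpenalized).
    Returns the coefficient vector including the leading intercept.
    """
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        A = (Xd * w[:, None]).T @ Xd + np.diag(pen) * n
        b = (Xd * w[:, None]).T @ z
        new = np.linalg.solve(A, b)
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            return beta
    raise IRLSError(
        f"IRLS did not converge within {max_iter} iterations (ridge={ridge})"
    )


def lr_beta_scores(X: pd.DataFrame, y) -> pd.Series:
    """|standardized coefficient| from one multivariable ridge-stabilized
    logistic fit.  Constant columns score 0 (flagged degenerate upstream)."""
    yv = _check_y(np.asarray(y))
    Z, const = _standardize(X.to_numpy(dtype=float))
    Z = Z[:, ~const]
    beta = fit_logistic_irls(Z, yv)
    scores = np.zeros(X.shape[1])
    scores[~const] = np.abs(beta[1:])
    return pd.Series(scores, index=X.columns, name="lr_beta")


def relief_scores(X: pd.DataFrame, y, k_neighbors: int = 10) -> pd.Series:
    """ReliefF weights for a binary outcome.

    Every instance contributes; neighbors are found by Manhattan distance on
    features scaled to [0, 1] (constant features scale to 0 everywhere and
    receive weight 0).  W(f) = mean over instances of
    [mean diff(f, x, k nearest misses) - mean diff(f, x, k nearest hits)].
    """
    yv = _check_y(np.asarray(y))
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    lo, hi = Xv.min(axis=0), Xv.max(axis=0)
    rng_span = np.where(hi > lo, hi - lo, 1.0)
    S = (Xv - lo) / rng_span

    for cls in (0.0, 1.0):
        if int((yv == cls).sum()) < k_neighbors + 1:
            raise ValueError(
                f"class {int(cls)} has fewer than k_neighbors+1="
                f"{k_neighbors + 1} instances; use a smaller k_neighbors"
            )

    W = np.zeros(p)
    idx_by_class = {c: np.flatnonzero(yv == c) for c in (0.0, 1.0)}
    # chunked all-pairs Manhattan distances to bound memory at n~5000
    chunk = max(1, int(2e7 // max(n * p, 1)))
    for start in range(0, n, chunk):
        rows = np.arange(start, min(start + chunk, n))
        D = np.abs(S[rows, None, :] - S[None, :, :]).sum(axis=2)
        for ri, i in enumerate(rows):
            same = idx_by_class[yv[i]]
            other = idx_by_class[1.0 - yv[i]]
            d_same = D[ri, same]
            # exclude self by position, keep duplicates of other rows
            self_pos = np.flatnonzero(same == i)[0]
            d_same = np.delete(d_same, self_pos)
            hits_pool = np.delete(same, self_pos)
            hit_order = np.argsort(d_same, kind="stable")[:k_neighbors]
            miss_order = np.argsort(D[ri, other], kind="stable")[:k_neighbors]
            hits = hits_pool[hit_order]
            misses = other[miss_order]
            W += np.abs(S[misses] - S[i]).mean(axis=0)
            W -= np.abs(S[hits] - S[i]).mean(axis=0)
    return pd.Series(W / n, index=X.columns, name="relief")


def _entropy_bits(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def infgain_scores(X: pd.DataFrame, y, n_bins: int = 10) -> pd.Series:
    """Information gain of the outcome from each feature, in bits.

    Numeric features are discretized into `n_bins` equal-frequency bins
    (duplicate bin edges merged, empty bins dropped); features with at most
    two distinct values are used as-is.
    """
    yv = _check_y(np.asarray(y)).astype(int)
    h_y = _entropy_bits(np.bincount(yv, minlength=2).astype(float))
    out = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        uniq = np.unique(x)
        if uniq.size <= 2:
            codes = np.searchsorted(uniq, x)
        else:
            binned = pd.qcut(x, q=n_bins, duplicates="drop")
            codes = binned.codes
        h_cond = 0.0
        n = len(x)
        for v in np.unique(codes):
            sel = codes == v
            h_cond += sel.sum() / n * _entropy_bits(
                np.bincount(yv[sel], minlength=2).astype(float)
            )
        out[col] = h_y - h_cond
    return pd.Series(out, name="infgain")


@dataclass
class FeatureScoreTable:
    """Per-feature filter scores, normalized scores, aggregate and rank."""

    table: pd.DataFrame
    aggregation: str  # "score_mean" or "rank_mean"
    degenerate_methods: list[str]

    def top(self, k: int = 18) -> pd.DataFrame:
        """The k best-ranked features (the published-table analogue)."""
        return self.table.nsmallest(k, "rank")

    def indicator_fraction_top(self, k: int = 18) -> float:
        """Fraction of the top-k features that are missingness indicators."""
        top = self.top(k)
        return float(top["is_indicator"].mean())


def _minmax(s: pd.Series) -> tuple[pd.Series, bool]:
    lo, hi = s.min(), s.max()
    if hi == lo:
        return pd.Series(0.5, index=s.index), True
    return (s - lo) / (hi - lo), False


def ensemble_rank(
    X: pd.DataFrame,
    y,
    k_neighbors: int = 10,
    n_bins: int = 10,
    aggregation: str = "score_mean",
) -> FeatureScoreTable:
    """Run the three filter scorers and aggregate them into one ranking.

    aggregation="score_mean" (default) averages the min-max normalized
    scores; "rank_mean" averages the within-method ranks instead (then
    renormalizes so larger is better).  A method whose scores are all equal
    is degenerate: it contributes 0.5 to every feature and is flagged.
    Rank ties are broken lexicographically by feature name.
    """
    if aggregation not in ("score_mean", "rank_mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    raw = pd.DataFrame(
        {
            "lr_beta": lr_beta_scores(X, y),
            "relief": relief_scores(X, y, k_neighbors=k_neighbors),
            "infgain": infgain_scores(X, y, n_bins=n_bins),
        }
    )
    degenerate = []
    norm = {}
    for m in raw.columns:
        norm_s, degen = _minmax(raw[m])
        if degen:
            degenerate.append(m)
        norm[m] = norm_s
    normdf = pd.DataFrame(norm)
    if aggregation == "score_mean":
        aggregate = normdf.mean(axis=1)
    else:
        ranks = raw.rank(ascending=False, method="average")
        aggregate = 1.0 - (ranks.mean(axis=1) - 1.0) / max(len(raw) - 1, 1)
    table = pd.concat(
        [raw.add_prefix("raw_"), normdf.add_prefix("norm_")], axis=1
    )
    table["aggregate"] = aggregate
    # deterministic tie-break: aggregate desc, then feature name asc
    order = table.reindex(
        sorted(table.index, key=lambda f: (-table.loc[f, "aggregate"], f))
    )
    order["rank"] = np.arange(1, len(order) + 1)
    order["is_indicator"] = [c.startswith(INDICATOR_PREFIX) for c in order.index]
    return FeatureScoreTable(
        table=order, aggregation=aggregation, degenerate_methods=degenerate
    )
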