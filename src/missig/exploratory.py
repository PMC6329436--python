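"""Exploratory battery for missingness structure.

Covers: per-test missingness rates, pairwise phi correlation among
missingness indicators with connected-component group detection at a high
threshold (the co-ordering panels reappear as phi blocks), Spearman
correlation of per-patient missing-test counts with the severity score
(negative under MNAR: sicker patients get more tests), and per-indicator
association with each mortality outcome.

Phi on a constant vector is undefined; it is reported as NaN and flagged,
never coerced to 0 — a test everyone (or no one) received carries no
association information and a silent zero would distort rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "phi",
    "phi_matrix",
    "find_groups",
    "missingness_rates",
    "spearman_missing_vs_severity",
    "indicator_outcome_association",
    "ExploratoryReport",
    "explore_day",
]


class ConstantVectorError(ValueError):
    """Phi (or Spearman) is undefined on a constant input."""


def phi(a, b) -> float:
    """Phi coefficient of two binary vectors from their 2x2 table.

    phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0); identical to
    the Pearson correlation of the two 0/1 vectors.  Raises
    :class:`ConstantVectorError` when either vector is constant.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("phi needs two equal-length 1-d vectors of length >= 2")
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    if r1 == 0 or r0 == 0 or c1 == 0 or c0 == 0:
        raise ConstantVectorError("phi undefined: a constant vector was given")
    return float((n11 * n00 - n10 * n01) / np.sqrt(float(r1) * r0 * c1 * c0))


def _phi_or_nan(a, b) -> float:
    try:
        return phi(a, b)
    except ConstantVectorError:
        return float("nan")


def phi_matrix(indicators: pd.DataFrame) -> pd.DataFrame:
    """Symmetric phi matrix among indicator columns.

    Implemented as the Pearson correlation of the 0/1 columns (an exact
    identity for binary data); constant columns yield NaN rows/columns
    (flagged undefined).  The diagonal is 1 where defined.
    """
    X = indicators.to_numpy(dtype=float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.corrcoef(X, rowvar=False)
    M = np.asarray(M, dtype=float)
    M[sd == 0, :] = np.nan
    M[:, sd == 0] = np.nan
    return pd.DataFrame(M, index=indicators.columns, columns=indicators.columns)


def find_groups(phi_df: pd.DataFrame, threshold: float = 0.95) -> list[list[str]]:
    """Maximal connected components of the graph with edges at phi >= threshold.

    Components are connected, not necessarily cliques.  Singleton components
    are omitted.  Output is invariant to column order: groups are sorted by
    name internally and by their first member externally.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    names = list(phi_df.columns)
    A = phi_df.to_numpy(dtype=float)
    adj = np.nan_to_num(A, nan=-np.inf) >= threshold
    np.fill_diagonal(adj, False)
    n = len(names)
    comp = -np.ones(n, dtype=int)
    cid = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = cid
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if comp[v] < 0:
                    comp[v] = cid
                    stack.append(v)
        cid += 1
    groups = []
    for c in range(cid):
        members = sorted(names[i] for i in np.flatnonzero(comp == c))
        if len(members) > 1:
            groups.append(members)
    return sorted(groups)


def missingness_rates(indicators: pd.DataFrame) -> pd.Series:
    """Per-test fraction absent: the column means of the indicator matrix."""
    rates = indicators.mean()
    rates.name = "missingness_rate"
    return rates


def spearman_missing_vs_severity(
    indicators: pd.DataFrame, severity: pd.Series
) -> tuple[float, float]:
    """Spearman rho (and two-sided p) between per-patient missing-test count
    and the severity score.  Ties are midranked; p uses the large-sample t
    approximation."""
    counts = indicators.sum(axis=1).to_numpy(dtype=float)
    sev = severity.to_numpy(dtype=float)
    if counts.size < 10:
        raise ValueError("need at least 10 patients")
    if np.all(sev == sev[0]) or np.all(counts == counts[0]):
        raise ConstantVectorError("Spearman undefined on a constant input")
    rho, p = stats.spearmanr(counts, sev)
    return float(rho), float(p)


def indicator_outcome_association(
    indicators: pd.DataFrame, outcome: pd.Series
) -> pd.Series:
    """Phi between each indicator column and a binary outcome.

    Constant indicator columns are flagged undefined (NaN).
    """
    y = outcome.to_numpy()
    if len(np.unique(y)) < 2:
        raise ConstantVectorError("outcome is constant")
    out = pd.Series(
        {c: _phi_or_nan(indicators[c].to_numpy(), y) for c in indicators.columns},
        name="phi",
    )
    return out


@dataclass
class ExploratoryReport:
    """All exploratory statistics for one cohort day."""

    day: int
    missingness_rate: pd.Series
    phi: pd.DataFrame
    groups: list[list[str]]
    spearman_severity: tuple[float, float]
    indicator_outcome_phi: pd.DataFrame  # indicators x outcomes


def explore_day(
    day_index: int,
    indicators: pd.DataFrame,
    severity: pd.Series,
    outcomes: pd.DataFrame,
    group_threshold: float = 0.95,
) -> ExploratoryReport:
    """Run the full exploratory battery on one day's indicator matrix."""
    pm = phi_matrix(indicators)
    assoc = pd.DataFrame(
        {o: indicator_outcome_association(indicators, outcomes[o]) for o in outcomes}
    )
    return ExploratoryReport(
        day=day_index,
        missingness_rate=missingness_rates(indicators),
        phi=pm,
        groups=find_groups(pm, group_threshold),
        spearman_severity=spearman_missing_vs_severity(indicators, severity),
        indicator_outcome_phi=assoc,
    )
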