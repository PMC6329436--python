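"""Hot-deck and predictive-mean-matching (PMM) imputation.

Both methods are donor-based: every filled cell takes an *observed* value of
the same column from some donor patient, never a synthetic number, so the
marginal distribution of each column is drawn from real (here: simulated
but actually measured) values.

* Hot deck fills a cell with the value from the nearest donor, where
  "nearest" is root-mean-square distance over the standardized columns the
  recipient and donor are both observed on.
* PMM regresses the target column on the other columns, then borrows the
  observed value of one of the k donors whose predicted means are closest
  to the recipient's predicted mean.

Both methods accept a separate donor/training frame so they can be fitted
on cross-validation training folds and applied to held-out rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ImputationSpec", "ImputedMatrix", "hot_deck_impute", "pmm_impute", "impute"]

logger = logging.getLogger(__name__)

_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class ImputationSpec:
    """Method choice and knobs for one imputation run.

    pmm_donors is the PMM donor-pool size k; rng_seed drives every random
    tie-break and donor draw (keyed per column and consumed in stable
    patient-id order, so results are invariant to row permutation).
    """

    method: str = "pmm"
    pmm_donors: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("hot_deck", "pmm"):
            raise ValueError(f"method must be 'hot_deck' or 'pmm', got {self.method!r}")
        if self.pmm_donors < 1:
            raise ValueError(f"pmm_donors must be >= 1, got {self.pmm_donors}")
        if self.rng_seed < 0:
            raise ValueError("rng_seed must be non-negative")


@dataclass
class ImputedMatrix:
    """A completed value matrix plus the provenance of every filled cell."""

    values: pd.DataFrame
    imputed_mask: pd.DataFrame  # bool, True where the cell was filled
    method: str

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("ImputedMatrix must not contain absent entries")


def _column_rng(seed: int, col_index: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tag, col_index]))


def _stable_order(index: pd.Index) -> np.ndarray:
    """Positions of `index` sorted by patient id (row-permutation invariant)."""
    return np.argsort(index.to_numpy(), kind="stable")


def hot_deck_impute(
    raw: pd.DataFrame,
    spec: ImputationSpec | None = None,
    donors: pd.DataFrame | None = None,
) -> ImputedMatrix:
    """Nearest-donor hot-deck imputation of `raw`.

    Donors default to `raw` itself (a row never donates to itself).  Column
    standardization statistics come from the donor frame.  Ties among
    equally near donors are broken by a seeded uniform draw; a recipient
    sharing no observed column with any eligible donor falls back to a
    seeded random observed donor (logged).
    """
    spec = spec or ImputationSpec(method="hot_deck")
    self_donate = donors is None
    donors = raw if self_donate else donors
    if list(donors.columns) != list(raw.columns):
        raise ValueError("donor frame must share the recipient frame's columns")

    empty = [c for c in raw.columns if donors[c].notna().sum() == 0]
    if empty:
        raise ValueError(f"no donor pool: columns with zero observed values: {empty}")

    mu = donors.mean()
    sd = donors.std(ddof=0).replace(0.0, 1.0).fillna(1.0)
    Zr = ((raw - mu) / sd).to_numpy(dtype=float)
    Zd = ((donors - mu) / sd).to_numpy(dtype=float)
    Mr, Md = np.isfinite(Zr), np.isfinite(Zd)
    Ar, Ad = np.where(Mr, Zr, 0.0), np.where(Md, Zd, 0.0)
    Br, Bd = Ar**2, Ad**2
    # squared distance summed over co-observed columns, and co-observed counts
    S = Br @ Md.T + Mr @ Bd.T - 2.0 * Ar @ Ad.T
    C = (Mr.astype(np.int32) @ Md.T.astype(np.int32)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.sqrt(np.maximum(S, 0.0) / C)
    D[C == 0] = np.inf

    values = raw.to_numpy(dtype=float).copy()
    mask = ~np.isfinite(values)
    donor_vals = donors.to_numpy(dtype=float)
    donor_ids = donors.index.to_numpy()
    order = _stable_order(raw.index)
    raw_ids = raw.index.to_numpy()

    for j, col in enumerate(raw.columns):
        missing_rows = [i for i in order if mask[i, j]]
        if not missing_rows:
            continue
        rng = _column_rng(spec.rng_seed, j, tag=101)
        pool = np.flatnonzero(Md[:, j])
        for i in missing_rows:
            cand = pool
            if self_donate:
                cand = cand[donor_ids[cand] != raw_ids[i]]
            if cand.size == 0:
                raise ValueError(f"no donor pool for column {col!r}")
            d = D[i, cand]
            if not np.isfinite(d).any():
                # no co-observed columns with any donor: random observed donor
                logger.info(
                    "hot_deck: patient %r has no co-observed columns for %r; "
                    "random donor fallback", raw_ids[i], col
                )
                tied = cand
            else:
                best = d.min()
                tied = cand[d <= best * (1 + _TIE_RTOL) + 1e-300]
            tied = tied[np.argsort(donor_ids[tied], kind="stable")]
            pick = tied[int(rng.integers(tied.size))]
            values[i, j] = donor_vals[pick, j]

    out = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    mask_df = pd.DataFrame(mask, index=raw.index, columns=raw.columns)
    return ImputedMatrix(values=out, imputed_mask=mask_df, method="hot_deck")


def pmm_impute(
    raw: pd.DataFrame,
    spec: ImputationSpec | None = None,
    train: pd.DataFrame | None = None,
) -> ImputedMatrix:
    """Predictive-mean-matching imputation of `raw`.

    For each target column a linear predictor on the remaining columns is
    fitted on the training rows observed for that column (absent predictors
    are pre-filled with training column means for the regression design
    only).  Each absent cell takes the observed value of one of the
    ``spec.pmm_donors`` training donors with the closest predicted mean,
    chosen by a seeded uniform draw.
    """
    spec = spec or ImputationSpec(method="pmm")
    train = raw if train is None else train
    if list(train.columns) != list(raw.columns):
        raise ValueError("training frame must share the recipient frame's columns")
    k = spec.pmm_donors

    col_means = train.mean()
    Xtr_full = train.fillna(col_means).to_numpy(dtype=float)
    Xre_full = raw.fillna(col_means).to_numpy(dtype=float)
    train_obs = train.notna().to_numpy()
    train_vals = train.to_numpy(dtype=float)
    train_ids = train.index.to_numpy()

    values = raw.to_numpy(dtype=float).copy()
    mask = ~np.isfinite(values)
    order = _stable_order(raw.index)
    ncols = raw.shape[1]

    for j, col in enumerate(raw.columns):
        missing_rows = [i for i in order if mask[i, j]]
        if not missing_rows:
            continue
        obs = np.flatnonzero(train_obs[:, j])
        if obs.size < max(2, k):
            raise ValueError(
                f"column {col!r}: donor pool of {obs.size} observed values is "
                f"smaller than max(2, k={k})"
            )
        other = [c for c in range(ncols) if c != j]
        Xd = np.column_stack([np.ones(obs.size), Xtr_full[np.ix_(obs, other)]])
        y = train_vals[obs, j]
        beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
        if rank < Xd.shape[1]:
            logger.info(
                "pmm: rank-deficient design for column %r (rank %d < %d); "
                "minimum-norm least-squares solution used", col, rank, Xd.shape[1]
            )
        pred_donor = Xd @ beta
        rng = _column_rng(spec.rng_seed, j, tag=202)
        for i in missing_rows:
            xi = np.concatenate(([1.0], Xre_full[i, other]))
            pred_i = xi @ beta
            gap = np.abs(pred_donor - pred_i)
            # k nearest by (gap, donor id) for a deterministic boundary
            sel = np.lexsort((train_ids[obs], gap))[:k]
            pick = obs[sel[int(rng.integers(sel.size))]]
            values[i, j] = train_vals[pick, j]

    out = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    mask_df = pd.DataFrame(mask, index=raw.index, columns=raw.columns)
    return ImputedMatrix(values=out, imputed_mask=mask_df, method="pmm")


def impute(
    raw: pd.DataFrame,
    spec: ImputationSpec,
    train: pd.DataFrame | None = None,
) -> ImputedMatrix:
    """Dispatch on ``spec.method``."""
    if spec.method == "hot_deck":
        return hot_deck_impute(raw, spec, donors=train)
    return pmm_impute(raw, spec, train=train)
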