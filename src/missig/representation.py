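"""Missingness-indicator representation of an incomplete value matrix.

The central representation move: an incomplete patient-by-test matrix is
split into (a) an *auxiliary* indicator matrix recording, per cell, whether
the measurement is absent (1) or present (0), and (b) an imputed value
matrix; their column-wise join is the *augmented* matrix, which lets a model
see both the measured values and the presence pattern — and distinguishes
imputed from actually-measured values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import INDICATOR_PREFIX
from .simulate import CohortDay

__all__ = [
    "build_indicator_matrix",
    "apply_eligibility_filter",
    "build_augmented_matrix",
    "indicator_columns",
    "value_columns",
    "EmptyCohortError",
    "AugmentationMismatchError",
]


class EmptyCohortError(ValueError):
    """The eligibility filter removed every patient."""


class AugmentationMismatchError(ValueError):
    """Indicator matrix disagrees with the imputation mask."""


def build_indicator_matrix(raw: pd.DataFrame) -> pd.DataFrame:
    """Binary indicator matrix of `raw`: 1 where absent (NaN), 0 where present.

    Columns are renamed ``I-<test>`` in the source column order.
    """
    ind = raw.isna().astype(np.int8)
    ind.columns = [INDICATOR_PREFIX + c for c in raw.columns]
    return ind


def apply_eligibility_filter(day: CohortDay) -> tuple[CohortDay, int]:
    """Drop patients with an entirely absent day row.

    Returns the filtered day and the number of patients removed.  Raises
    :class:`EmptyCohortError` if nobody remains.
    """
    keep = day.values.notna().any(axis=1)
    removed = int((~keep).sum())
    if not keep.any():
        raise EmptyCohortError(
            f"day {day.day}: all {len(keep)} patients have fully absent rows"
        )
    if removed == 0:
        return day, 0
    filtered = CohortDay(
        day=day.day,
        values=day.values.loc[keep],
        outcomes=day.outcomes.loc[keep],
        severity_score=day.severity_score.loc[keep],
    )
    return filtered, removed


def build_augmented_matrix(imputed, indicators: pd.DataFrame) -> pd.DataFrame:
    """Join imputed values with their indicator columns (values first).

    `imputed` is an :class:`~missig.imputation.ImputedMatrix`.  The build
    verifies the defining invariant — indicator ``I-t`` is 1 exactly where
    test ``t`` was imputed — and fails on the first offending cell.
    """
    values, mask = imputed.values, imputed.imputed_mask
    if not values.index.equals(indicators.index):
        raise AugmentationMismatchError("imputed and indicator matrices have different patients")
    expected_cols = [INDICATOR_PREFIX + c for c in values.columns]
    if list(indicators.columns) != expected_cols:
        raise AugmentationMismatchError(
            f"indicator columns {list(indicators.columns)[:3]}... do not match "
            f"value columns under the {INDICATOR_PREFIX!r} prefix"
        )
    disagree = mask.to_numpy(dtype=bool) != indicators.to_numpy(dtype=bool)
    if disagree.any():
        i, j = np.argwhere(disagree)[0]
        raise AugmentationMismatchError(
            f"indicator/mask mismatch at patient {values.index[i]!r}, "
            f"test {values.columns[j]!r}"
        )
    return pd.concat([values, indicators], axis=1)


def indicator_columns(matrix: pd.DataFrame) -> list[str]:
    """Columns of `matrix` that are missingness indicators."""
    return [c for c in matrix.columns if c.startswith(INDICATOR_PREFIX)]


def value_columns(matrix: pd.DataFrame) -> list[str]:
    """Columns of `matrix` that are measured/imputed values."""
    return [c for c in matrix.columns if not c.startswith(INDICATOR_PREFIX)]
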