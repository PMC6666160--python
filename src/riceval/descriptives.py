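"""Per-index difference analysis: min, max, mean, SD and variable coefficient.

The variable coefficient (coefficient of variation) is sd/mean x 100 and
keeps the sign of the mean, so indexes with negative means (a* value,
adhesiveness) report negative CVs; ranking uses |CV|.  SD uses the sample
(n-1) denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .io import validate_table

__all__ = ["summarize", "rank_by_cv", "variable_coefficient"]

SUMMARY_COLUMNS = ["min", "max", "mean", "sd", "cv"]


def variable_coefficient(mean: float, sd: float) -> float:
    """CV in percent, signed like the mean; NaN when the mean is zero."""
    if mean == 0:
        return float("nan")
    return sd / mean * 100.0


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary per index column.

    Returns a frame indexed by column name with columns
    ``min, max, mean, sd, cv`` (cv in percent).  A column whose mean is
    exactly zero gets ``cv = NaN`` rather than infinity.
    """
    validate_table(table, min_samples=2)
    counts = table.count()
    if (counts < 2).any():
        bad = counts.index[counts < 2].tolist()
        raise InsufficientDataError(
            f"column(s) with fewer than 2 values: {', '.join(bad)}"
        )
    mean = table.mean()
    sd = table.std(ddof=1)
    cv = pd.Series(
        [variable_coefficient(m, s) for m, s in zip(mean, sd)],
        index=table.columns,
    )
    return pd.DataFrame(
        {"min": table.min(), "max": table.max(), "mean": mean, "sd": sd, "cv": cv},
        columns=SUMMARY_COLUMNS,
    )


def rank_by_cv(summary: pd.DataFrame, subset: list[str]) -> list[str]:
    """Order *subset* by decreasing |CV|.

    Ties are broken by position in *summary* (schema order).  Raises
    ``KeyError`` for an index absent from the summary.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    missing = [s for s in subset if s not in summary.index]
    if missing:
        raise KeyError(f"unknown index name(s): {', '.join(missing)}")
    order = {name: i for i, name in enumerate(summary.index)}
    return sorted(subset, key=lambda s: (-abs(summary.at[s, "cv"]), order[s]))


def to_report(summary: pd.DataFrame) -> pd.DataFrame:
    """Summary in the published column order, ready for CSV export."""
    out = summary.copy()
    out.columns = ["Minimum", "Maximum", "Mean", "SD", "Variable coefficient (%)"]
    return out
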