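"""Pearson correlation between quality indexes with significance flags.

Each pair is tested two-sided via the exact t transform
``t = r * sqrt(n-2) / sqrt(1-r^2)`` with ``df = n-2``, flagged at the
strongest level passed (``**`` for alpha=0.01, ``*`` for alpha=0.05).  No
multiple-testing correction is applied: the published pair counts are raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import validate_table

__all__ = [
    "CorrelationMatrix",
    "FlagMatrix",
    "correlation_matrix",
    "flag_significance",
    "count_flags",
    "critical_r",
]

NONE, P05, P01 = "", "*", "**"


@dataclass(frozen=True)
class CorrelationMatrix:
    names: tuple[str, ...]
    r: np.ndarray          # symmetric, unit diagonal
    n: int                 # sample count behind r

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.shape != (len(self.names),) * 2:
            raise ValidationError("correlation matrix shape does not match names")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValidationError("correlation matrix is not symmetric")
        if np.nanmax(np.abs(r)) > 1 + 1e-9:
            raise ValidationError("|r| exceeds 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.names, columns=self.names)


@dataclass(frozen=True)
class FlagMatrix:
    names: tuple[str, ...]
    flags: np.ndarray      # dtype=object over {'', '*', '**'}; diagonal ''
    alphas: tuple[float, float] = (0.05, 0.01)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flags, index=self.names, columns=self.names)


def correlation_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pearson product-moment correlation over the index columns."""
    validate_table(table, min_samples=3)
    sd = table.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValidationError(
            f"zero-variance column(s), correlation undefined: {', '.join(bad)}"
        )
    r = np.corrcoef(table.values, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(tuple(table.columns), r, len(table))


def critical_r(n: int, alpha: float) -> float:
    """|r| above which a two-sided test with df = n-2 rejects at *alpha*."""
    if n < 3:
        raise ValidationError("need n >= 3 for a correlation test")
    t_crit = stats.t.ppf(1 - alpha / 2, n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def flag_significance(cm: CorrelationMatrix) -> FlagMatrix:
    """Two-level significance flags for every off-diagonal pair.

    ``|r| = 1`` is flagged ``**`` directly (the t statistic is infinite).
    """
    if cm.n < 3:
        raise ValidationError("need n >= 3 to flag significance")
    r05, r01 = critical_r(cm.n, 0.05), critical_r(cm.n, 0.01)
    absr = np.abs(cm.r)
    flags = np.where(absr > r01, P01, np.where(absr > r05, P05, NONE)).astype(object)
    np.fill_diagonal(flags, NONE)
    return FlagMatrix(cm.names, flags)


def count_flags(fm: FlagMatrix) -> tuple[int, int, int]:
    """(total pairs, pairs significant at 0.05 only, pairs at 0.01).

    Counts run over the strict lower triangle; the middle count excludes
    pairs that reach the 0.01 level.
    """
    tri = np.tril_indices(len(fm.names), -1)
    vals = fm.flags[tri]
    return len(vals), int((vals == P05).sum()), int((vals == P01).sum())


def annotated_frame(cm: CorrelationMatrix, fm: FlagMatrix,
                    decimals: int = 3) -> pd.DataFrame:
    """r values with '*'/'**' suffixes, mirroring the published layout."""
    out = np.empty(cm.r.shape, dtype=object)
    for i in range(len(cm.names)):
        for j in range(len(cm.names)):
            out[i, j] = f"{cm.r[i, j]:.{decimals}f}{fm.flags[i, j]}"
    return pd.DataFrame(out, index=cm.names, columns=cm.names)
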