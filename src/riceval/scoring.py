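"""Composite quality scoring: Y = sum(Xi * Wi), ranking and distributions.

The comprehensive evaluation value of a sample is the dot product of its
standardized index scores with the index weights.  The shipped default
weights are the published model-formula coefficients
(0.5650, 0.2294, 0.0328, 0.1175, 0.0533 for palatability, adhesiveness,
resilience, b* value, iodine color value); a freshly composed AHP variant
(0.0553 for iodine color value) is available.  Formula weights sum to
0.998 and are deliberately not renormalized by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .descriptives import variable_coefficient
from .errors import InsufficientDataError, ValidationError
from . import fixtures

__all__ = ["comprehensive_score", "rank_samples", "distribution_summary",
           "HISTOGRAM_EDGES", "ScoreDistribution"]

log = logging.getLogger(__name__)

#: Half-open bins [0.1,0.2) ... [0.6,0.7), closed last bin [0.7, 1].
HISTOGRAM_EDGES = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 1.0]


def comprehensive_score(
    X: pd.DataFrame,
    weights: dict[str, float] | None = None,
    *,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Weighted composite score per sample.

    Parameters
    ----------
    X
        Standardized scores in [0, 1], one column per index.
    weights
        Index -> weight.  Defaults to the published formula coefficients.
        Must cover exactly the columns of *X*.
    renormalize
        Rescale weights to sum to 1 (off by default; a warning is logged
        when the supplied weights do not sum to 1).

    Returns a frame with one ``Y`` column plus per-index ``w_<index>``
    contribution columns (Xi * Wi), full precision.
    """
    weights = dict(weights) if weights is not None else fixtures.load_fixture("paper_weights")
    diff = set(X.columns) ^ set(weights)
    if diff:
        raise ValidationError(
            f"index mismatch between scores and weights: {sorted(diff)}"
        )
    total = sum(weights.values())
    if renormalize:
        weights = {k: v / total for k, v in weights.items()}
    elif abs(total - 1.0) > 1e-9:
        log.warning("weights sum to %.4f, not 1; proceeding unrenormalized", total)

    cols = list(X.columns)
    w = np.array([weights[c] for c in cols])
    contrib = X[cols].values * w
    out = pd.DataFrame(contrib, index=X.index,
                       columns=[f"w_{c}" for c in cols])
    out.insert(0, "Y", contrib.sum(axis=1))
    return out


def rank_samples(scores: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Order samples by descending Y with competition ranking.

    Ties share the minimum rank and the next rank is skipped
    (1, 1, 3, ...).  Returns a frame with ``Y`` and ``rank`` sorted best
    first.
    """
    y = scores["Y"] if isinstance(scores, pd.DataFrame) else scores
    if len(y) == 0:
        raise ValidationError("no samples to rank")
    rank = y.rank(method="min", ascending=False).astype(int)
    out = pd.DataFrame({"Y": y, "rank": rank})
    return out.sort_values(["rank", "Y"], ascending=[True, False])


@dataclass(frozen=True)
class ScoreDistribution:
    n: int
    min: float
    max: float
    mean: float
    sd: float
    cv: float
    skewness: float        # bias-adjusted sample estimator
    kurtosis: float        # bias-adjusted, excess
    histogram: tuple       # counts over HISTOGRAM_EDGES bins

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("n", "min", "max", "mean", "sd", "cv", "skewness", "kurtosis")}
        d["histogram"] = {
            f"[{lo:g}, {hi:g}{']' if hi == HISTOGRAM_EDGES[-1] else ')'}": c
            for lo, hi, c in zip(HISTOGRAM_EDGES, HISTOGRAM_EDGES[1:], self.histogram)
        }
        return d


def distribution_summary(scores: pd.DataFrame | pd.Series) -> ScoreDistribution:
    """Moments and fixed-bin histogram of composite scores.

    Skewness needs n >= 3 and kurtosis n >= 4; below that the estimator is
    reported as NaN (partial summary), and n < 2 raises.
    """
    y = np.asarray(scores["Y"] if isinstance(scores, pd.DataFrame) else scores,
                   dtype=float)
    n = len(y)
    if n < 2:
        raise InsufficientDataError("need at least 2 scores for a distribution summary")
    mean = float(y.mean())
    sd = float(y.std(ddof=1))
    skew = float(stats.skew(y, bias=False)) if n >= 3 else float("nan")
    kurt = float(stats.kurtosis(y, bias=False, fisher=True)) if n >= 4 else float("nan")
    hist, _ = np.histogram(y, bins=HISTOGRAM_EDGES)
    return ScoreDistribution(
        n=n, min=float(y.min()), max=float(y.max()),
        mean=mean, sd=sd, cv=variable_coefficient(mean, sd),
        skewness=skew, kurtosis=kurt, histogram=tuple(int(c) for c in hist),
    )
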