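"""Analytic hierarchy process: eigenvector weights and consistency checks.

A pairwise comparison ("discriminant") matrix records judgments on Saaty's
1-9 scale: ``a[i][j]`` is how much more element *i* contributes than *j*,
with exact reciprocity ``a[j][i] = 1/a[i][j]``.  Priorities are the
normalized principal right eigenvector, found by power iteration.  The
consistency index ``CI = (lambda_max - n)/(n - 1)`` is compared with the
expected CI of random matrices of the same order (the random index RI);
the judgment set is accepted when ``CR = CI/RI < 0.1``.  Matrices of order
1 or 2 are consistent by construction (CR defined as 0).

A two-level hierarchy composes: global leaf weight = criterion weight x
local weight within the criterion, with an implicit local weight of 1 for
single-child criteria.  Alongside per-matrix CRs the composer reports the
total-ordering CR of the hierarchy,
``(CI_criterion + sum_j w_j CI_j) / (RI_criterion + sum_j w_j RI_j)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import ValidationError

__all__ = [
    "PairwiseMatrix", "ConsistencyReport", "Hierarchy", "ComposedWeights",
    "principal_weights", "consistency", "compose",
    "RANDOM_INDEX", "RANDOM_INDEX_SAATY",
]

#: Expected consistency index of random reciprocal matrices, by order.
#: Default table (order 4 -> 0.89) matches the published CR = 0.0438;
#: Saaty's variant (order 4 -> 0.90) is available for comparison.
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.89, 5: 1.12,
                6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}
RANDOM_INDEX_SAATY = {**RANDOM_INDEX, 4: 0.90}


@dataclass(frozen=True)
class PairwiseMatrix:
    labels: tuple[str, ...]
    a: np.ndarray = field(compare=False)   # positive reals, reciprocal

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        n = len(self.labels)
        if a.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if np.any(a <= 0):
            raise ValidationError("pairwise entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=1e-12):
            raise ValidationError("diagonal entries must be 1")
        if not np.allclose(a * a.T, 1.0, rtol=1e-9):
            raise ValidationError("matrix is not reciprocal (a[j][i] != 1/a[i][j])")
        if np.any(a > 9 + 1e-9) or np.any(a < 1 / 9 - 1e-9):
            raise ValidationError("entries must lie on the 1-9 scale ([1/9, 9])")
        object.__setattr__(self, "a", a)

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_rationals(cls, labels, rows) -> "PairwiseMatrix":
        """Build from exact rationals (``Fraction`` or strings like '1/7')."""
        a = np.array([[float(Fraction(x)) for x in row] for row in rows])
        return cls(tuple(labels), a)


@dataclass(frozen=True)
class ConsistencyReport:
    lambda_max: float
    CI: float
    RI: float
    CR: float

    @property
    def acceptable(self) -> bool:
        return self.CR < 0.1


def principal_weights(
    m: PairwiseMatrix,
    *,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> tuple[dict[str, float], float]:
    """Normalized principal eigenvector of a pairwise matrix, with λmax.

    Power iteration on the positive matrix; by Perron-Frobenius the
    dominant eigenvector is positive and unique, so convergence is
    guaranteed for valid input (a guard raises after *max_iter* anyway).
    """
    a = m.a
    w = np.full(m.n, 1.0 / m.n)
    for _ in range(max_iter):
        w_new = a @ w
        w_new /= w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    else:
        raise ValidationError("power iteration failed to converge")
    lambda_max = float((a @ w).sum() / w.sum())
    return dict(zip(m.labels, w.tolist())), lambda_max


def consistency(
    m: PairwiseMatrix,
    *,
    random_index: dict[int, float] = RANDOM_INDEX,
) -> ConsistencyReport:
    """λmax, CI, RI and CR for a pairwise matrix."""
    _, lambda_max = principal_weights(m)
    if m.n <= 2:
        return ConsistencyReport(lambda_max, 0.0, 0.0, 0.0)
    CI = (lambda_max - m.n) / (m.n - 1)
    try:
        RI = random_index[m.n]
    except KeyError:
        raise ValidationError(f"no random index for order {m.n}") from None
    return ConsistencyReport(lambda_max, CI, RI, CI / RI)


@dataclass(frozen=True)
class Hierarchy:
    """Two-level AHP hierarchy: criteria over leaf indexes.

    ``children`` maps each criterion label to its leaf labels;
    ``sub_matrices`` holds a PairwiseMatrix for every multi-child
    criterion (single children get implicit local weight 1).
    """

    criterion_matrix: PairwiseMatrix
    children: dict
    sub_matrices: dict

    def __post_init__(self):
        leaves = [leaf for c in self.criterion_matrix.labels
                  for leaf in self.children.get(c, [])]
        if len(set(leaves)) != len(leaves):
            raise ValidationError("a leaf appears under more than one criterion")
        if not leaves:
            raise ValidationError("hierarchy has no leaves")
        for c in self.criterion_matrix.labels:
            kids = self.children.get(c, [])
            if not kids:
                raise ValidationError(f"criterion {c!r} has no leaves")
            if len(kids) > 1:
                if c not in self.sub_matrices:
                    raise ValidationError(f"criterion {c!r} needs a sub-matrix")
                if tuple(self.sub_matrices[c].labels) != tuple(kids):
                    raise ValidationError(
                        f"sub-matrix labels for {c!r} do not match its leaves"
                    )

    @property
    def leaves(self) -> list[str]:
        return [leaf for c in self.criterion_matrix.labels
                for leaf in self.children[c]]


@dataclass(frozen=True)
class ComposedWeights:
    weights: dict                      # leaf -> global weight, sums to 1
    criterion_weights: dict            # criterion -> weight
    reports: dict                      # matrix name -> ConsistencyReport
    total_ordering_CR: float

    @property
    def acceptable(self) -> bool:
        return (all(r.acceptable for r in self.reports.values())
                and self.total_ordering_CR < 0.1)


def compose(
    h: Hierarchy,
    *,
    random_index: dict[int, float] = RANDOM_INDEX,
    allow_inconsistent: bool = False,
) -> ComposedWeights:
    """Global leaf weights from a two-level hierarchy.

    Every matrix must pass CR < 0.1 unless *allow_inconsistent* (then a
    warning is logged and composition proceeds).
    """
    import logging
    log = logging.getLogger(__name__)

    crit_w, _ = principal_weights(h.criterion_matrix)
    reports = {"criterion": consistency(h.criterion_matrix, random_index=random_index)}

    weights: dict[str, float] = {}
    ci_sum, ri_sum = reports["criterion"].CI, reports["criterion"].RI
    for c in h.criterion_matrix.labels:
        kids = h.children[c]
        if len(kids) == 1:
            weights[kids[0]] = crit_w[c]
        else:
            sub = h.sub_matrices[c]
            local, _ = principal_weights(sub)
            rep = consistency(sub, random_index=random_index)
            reports[c] = rep
            ci_sum += crit_w[c] * rep.CI
            ri_sum += crit_w[c] * rep.RI
            for leaf in kids:
                weights[leaf] = crit_w[c] * local[leaf]

    total_cr = ci_sum / ri_sum if ri_sum > 0 else 0.0
    composed = ComposedWeights(weights, crit_w, reports, total_cr)
    if not composed.acceptable:
        if not allow_inconsistent:
            bad = [k for k, r in reports.items() if not r.acceptable]
            raise ValidationError(
                f"consistency check failed (CR >= 0.1) for: {', '.join(bad) or 'total ordering'}"
            )
        log.warning("composing despite failed consistency check")
    return composed


def paper_hierarchy() -> Hierarchy:
    """The shipped hierarchy: four criteria over the five representatives."""
    from . import fixtures

    spec = fixtures.load_fixture("hierarchy")
    mats = fixtures.load_fixture("table7")

    def mat(name):
        m = mats[name]
        return PairwiseMatrix.from_rationals(m["labels"], m["matrix"])

    return Hierarchy(
        criterion_matrix=mat(spec["criterion_matrix"]),
        children=dict(spec["children"]),
        sub_matrices={c: mat(m) for c, m in spec["sub_matrices"].items()},
    )
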