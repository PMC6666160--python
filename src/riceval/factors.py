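"""Principal-component factor extraction with Kaiser retention and varimax.

Extraction is the principal-component method on a correlation matrix:
unrotated loadings are eigenvector columns scaled by sqrt(eigenvalue), and
a factor's contribution to total variance is eigenvalue / p (p = number of
indexes).  Factors with eigenvalue strictly greater than 1 are retained
(Kaiser criterion).  Rotation is orthogonal varimax with Kaiser row
normalization; it redistributes variance among the retained factors but
preserves each index's communality and the cumulative retained variance.

Because extraction needs only the correlation matrix, the published matrix
can be factored directly — no raw data required.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .correlation import CorrelationMatrix
from .errors import ValidationError

__all__ = ["FactorModel", "extract_factors", "rotate_varimax", "assign_to_factors"]


@dataclass(frozen=True)
class FactorModel:
    names: tuple[str, ...]
    eigenvalues: np.ndarray       # all p eigenvalues, descending
    retained_k: int
    loadings: np.ndarray          # p x retained_k
    contribution: np.ndarray      # per retained factor, percent of p
    cumulative: np.ndarray        # running sum, percent
    rotated: bool = False

    @property
    def communalities(self) -> np.ndarray:
        """Row sums of squared loadings (invariant under rotation)."""
        return (self.loadings**2).sum(axis=1)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"f{i + 1}" for i in range(self.retained_k)]
        return pd.DataFrame(self.loadings, index=self.names, columns=cols)


def _sign_convention(L: np.ndarray) -> np.ndarray:
    """Flip each factor so its largest-|loading| entry is positive."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] *= -1
    return L


def extract_factors(cm: CorrelationMatrix | pd.DataFrame,
                    *, k: int | None = None) -> FactorModel:
    """Eigendecompose a correlation matrix and retain factors with λ > 1.

    ``k`` overrides Kaiser retention.  The input must be symmetric with a
    unit diagonal; slightly indefinite matrices (3-dp published values) are
    accepted as long as eigenvalues are above ``-1e-8`` — repair genuinely
    indefinite input with :func:`riceval.synthetic.nearest_correlation`
    first.
    """
    if isinstance(cm, CorrelationMatrix):
        names, r = cm.names, cm.r
    else:
        names, r = tuple(cm.index), cm.values
    r = np.asarray(r, dtype=float)
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValidationError("correlation matrix is not symmetric")
    r = (r + r.T) / 2.0
    p = r.shape[0]

    w, v = np.linalg.eigh(r)
    w, v = w[::-1], v[:, ::-1]
    if w[-1] < -1e-8:
        raise ValidationError(
            f"matrix is indefinite (min eigenvalue {w[-1]:.3g}); "
            "repair with nearest_correlation first"
        )
    w = np.clip(w, 0.0, None)

    if k is None:
        k = int((w > 1.0).sum())
        if k == 0:
            raise ValidationError(
                "no eigenvalue exceeds 1; pass an explicit k to retain factors"
            )
    elif not 1 <= k <= p:
        raise ValidationError(f"k must be in [1, {p}]")

    loadings = _sign_convention(v[:, :k] * np.sqrt(w[:k]))
    contribution = w[:k] / p * 100.0
    return FactorModel(
        names=tuple(names),
        eigenvalues=w,
        retained_k=k,
        loadings=loadings,
        contribution=contribution,
        cumulative=np.cumsum(contribution),
    )


def rotate_varimax(model: FactorModel) -> FactorModel:
    """Varimax-rotate the retained loadings (Kaiser row normalization).

    With a single retained factor rotation is the identity.  Rotated
    factors are reordered by explained variance and sign-normalized; the
    per-factor contribution becomes the rotated sum of squared loadings
    over p, whose total (cumulative) is unchanged.
    """
    if model.retained_k < 2:
        return replace(model, rotated=True)
    # Kaiser normalization: rotate rows scaled to unit communality
    h = np.sqrt((model.loadings**2).sum(axis=1))
    h = np.where(h > 0, h, 1.0)
    L_norm, _ = rotate_factors(model.loadings / h[:, None], "varimax")
    L = L_norm * h[:, None]
    ssl = (L**2).sum(axis=0)
    order = np.argsort(ssl)[::-1]
    L, ssl = _sign_convention(L[:, order]), ssl[order]
    contribution = ssl / len(model.names) * 100.0
    return replace(
        model,
        loadings=L,
        contribution=contribution,
        cumulative=np.cumsum(contribution),
        rotated=True,
    )


def assign_to_factors(model: FactorModel) -> dict[str, int]:
    """Map each index to the factor with maximal |loading| (1-based ids).

    Ties go to the lower factor id.  Intended for a rotated model, where
    the loading pattern is simple structure.
    """
    absL = np.abs(model.loadings)
    return {
        name: int(np.argmax(absL[i])) + 1 for i, name in enumerate(model.names)
    }
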