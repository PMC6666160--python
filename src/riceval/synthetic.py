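"""Synthetic variety panels with the study's moment structure.

The raw 108 x 17 measurement matrix behind the published summaries is not
available, so testable stand-ins are drawn from a multivariate normal with
the published per-index means and SDs and the published correlation
matrix.  The printed 3-dp correlations may be slightly indefinite, so the
target matrix is first repaired to the nearest valid correlation matrix
(alternating projections).  Optional per-index truncation to the published
ranges is enforced by rejection sampling.

The moment-driven analysis chain (Pearson correlation, principal-component
factoring, Ward clustering) sees exactly the structure it assumes; bounded
or skewed marginals of real sensory scores are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

from .errors import ValidationError
from . import fixtures

__all__ = ["GeneratorSpec", "nearest_correlation", "generate", "paper_generator_spec"]


def nearest_correlation(m: np.ndarray | pd.DataFrame,
                        *, threshold: float = 1e-12) -> tuple[np.ndarray, float]:
    """Nearest positive-semidefinite correlation matrix.

    Returns ``(repaired, frobenius_distance)``.  A matrix that is already
    PSD (eigenvalues >= 0) is returned unchanged with distance 0.
    """
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("expected a square matrix")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("matrix is not symmetric")
    if not np.allclose(np.diag(a), 1.0, atol=1e-10):
        raise ValidationError("matrix does not have a unit diagonal")
    a = (a + a.T) / 2.0
    if np.linalg.eigvalsh(a)[0] >= 0:
        return a, 0.0
    repaired = corr_nearest(a, threshold=threshold, n_fact=200)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.linalg.norm(repaired - a, "fro"))


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic variety panel.

    Defaults (via :func:`paper_generator_spec`) are the published study
    conditions: 108 varieties, published means/SDs, published correlation
    structure.
    """

    names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    correlation: np.ndarray
    n_samples: int = 108
    seed: int = 0
    truncate: dict = field(default_factory=dict)   # name -> (lo, hi)

    def __post_init__(self):
        p = len(self.names)
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        corr = np.asarray(self.correlation, dtype=float)
        if means.shape != (p,) or sds.shape != (p,) or corr.shape != (p, p):
            raise ValidationError("means/sds/correlation shapes do not match names")
        if np.any(sds <= 0):
            raise ValidationError("all SDs must be positive")
        if self.n_samples < 2:
            raise ValidationError("n_samples must be at least 2")
        for name, (lo, hi) in self.truncate.items():
            i = self.names.index(name)
            if lo > means[i] - 6 * sds[i] and hi < means[i] + 6 * sds[i] and lo >= hi:
                raise ValidationError(f"infeasible truncation bounds for {name!r}")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "correlation", (corr + corr.T) / 2.0)


def paper_generator_spec(n_samples: int = 108, seed: int = 0,
                         *, truncate: bool = False) -> GeneratorSpec:
    """Spec with the published means, SDs and correlation structure."""
    t2 = fixtures.load_fixture("table2")
    r, _ = fixtures.load_fixture("table3")
    names = tuple(r.index)
    t2 = t2.loc[list(names)]
    bounds = ({n: (t2.at[n, "min"], t2.at[n, "max"]) for n in names}
              if truncate else {})
    return GeneratorSpec(
        names=names,
        means=t2["mean"].values,
        sds=t2["sd"].values,
        correlation=r.values,
        n_samples=n_samples,
        seed=seed,
        truncate=bounds,
    )


def generate(spec: GeneratorSpec) -> pd.DataFrame:
    """Draw a synthetic variety x index table per *spec*.

    Multivariate normal with covariance ``diag(sd) R diag(sd)`` (R repaired
    to PSD first); truncation, when requested, resamples offending rows.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    corr, _ = nearest_correlation(spec.correlation)
    cov = np.outer(spec.sds, spec.sds) * corr

    def draw(k: int) -> np.ndarray:
        return rng.multivariate_normal(spec.means, cov, size=k, method="eigh")

    x = draw(spec.n_samples)
    if spec.truncate:
        lo = np.full(len(spec.names), -np.inf)
        hi = np.full(len(spec.names), np.inf)
        for name, (a, b) in spec.truncate.items():
            i = spec.names.index(name)
            lo[i], hi[i] = a, b
        for _ in range(1000):
            bad = np.any((x < lo) | (x > hi), axis=1)
            if not bad.any():
                break
            x[bad] = draw(int(bad.sum()))
        else:
            raise ValidationError(
                "rejection sampling failed; truncation bounds exclude too much mass"
            )
    samples = [f"synthetic_{i + 1:03d}" for i in range(spec.n_samples)]
    out = pd.DataFrame(x, index=pd.Index(samples, name="sample"),
                       columns=list(spec.names))
    return out
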