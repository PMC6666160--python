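"""Packaged reference tables for the 108-variety japonica rice study.

The raw 108 x 17 measurement matrix was never published; what the study
prints — per-index descriptive statistics, the 17 x 17 correlation matrix
with significance flags, the rotated factor loadings, the dendrogram
5-class partition, the ideal values, the AHP discriminant matrices and the
nine verification samples — ships here as versioned plain-text fixtures.

Fractional pairwise-comparison entries (1/3, 1/5, 1/7) are stored as exact
rationals so reciprocity holds without decimal drift.

Use :func:`load_fixture` with one of: ``table2``, ``table3``, ``table4``,
``table5``, ``table7``, ``table9``, ``dendrogram_classes``, ``hierarchy``,
``paper_weights``, ``paper_weights_composed``.
"""

from __future__ import annotations

import json
from fractions import Fraction
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .errors import FixtureError, ValidationError

__all__ = ["load_fixture", "FIXTURE_NAMES"]


def _data(name: str):
    return resources.files("riceval.data").joinpath(name)


@lru_cache(maxsize=None)
def _table2() -> pd.DataFrame:
    with resources.as_file(_data("table2_descriptives.csv")) as p:
        return pd.read_csv(p, index_col="index")


@lru_cache(maxsize=None)
def _table3() -> tuple[pd.DataFrame, pd.DataFrame]:
    with resources.as_file(_data("table3_correlations.csv")) as p:
        r = pd.read_csv(p, index_col=0)
    with resources.as_file(_data("table3_flags.csv")) as p:
        flags = pd.read_csv(p, index_col=0, keep_default_na=False)
    # self-check: exact symmetry and unit diagonal as stored
    if not np.array_equal(r.values, r.values.T):
        raise ValidationError("table3 fixture is not symmetric")
    if not np.all(np.diag(r.values) == 1.0):
        raise ValidationError("table3 fixture diagonal is not 1")
    return r, flags


@lru_cache(maxsize=None)
def _table4() -> pd.DataFrame:
    with resources.as_file(_data("table4_loadings.csv")) as p:
        return pd.read_csv(p, index_col="index")


@lru_cache(maxsize=None)
def _table5() -> dict[str, float]:
    return json.loads(_data("table5_ideals.json").read_text())


@lru_cache(maxsize=None)
def _table7() -> dict:
    raw = json.loads(_data("table7_matrices.json").read_text())
    out = {}
    for key, spec in raw.items():
        a = [[Fraction(x) for x in row] for row in spec["matrix"]]
        n = len(a)
        for i in range(n):
            if a[i][i] != 1:
                raise ValidationError(f"table7 {key}: diagonal not 1")
            for j in range(n):
                if a[j][i] != 1 / a[i][j]:
                    raise ValidationError(
                        f"table7 {key}: entry ({j},{i}) is not the exact "
                        f"reciprocal of ({i},{j})"
                    )
        out[key] = {"labels": list(spec["labels"]), "matrix": a}
    return out


@lru_cache(maxsize=None)
def _table9() -> pd.DataFrame:
    with resources.as_file(_data("table9_verification.csv")) as p:
        t9 = pd.read_csv(p, index_col="sample")
    if t9.shape != (9, 6):
        raise ValidationError("table9 fixture must be 9 samples x (5 indexes + Y)")
    return t9


@lru_cache(maxsize=None)
def _weights() -> dict:
    return json.loads(_data("weights.json").read_text())


@lru_cache(maxsize=None)
def _dendrogram() -> dict[str, list[str]]:
    return json.loads(_data("dendrogram_classes.json").read_text())


@lru_cache(maxsize=None)
def _hierarchy() -> dict:
    return json.loads(_data("hierarchy.json").read_text())


_LOADERS = {
    "table2": _table2,                  # per-index min/max/mean/sd/cv
    "table3": _table3,                  # (r matrix, printed flag matrix)
    "table4": _table4,                  # rotated loadings, 17 x 5
    "table5": _table5,                  # ideal values x0 for the 5 representatives
    "table7": _table7,                  # AHP discriminant matrices (exact rationals)
    "table9": _table9,                  # 9 verification samples + printed Y
    "dendrogram_classes": _dendrogram,  # published 5-class tree-cut partition
    "hierarchy": _hierarchy,            # AHP hierarchy definition
    "paper_weights": lambda: dict(_weights()["paper_formula"]),
    "paper_weights_composed": lambda: dict(_weights()["paper_printed"]),
}

FIXTURE_NAMES = sorted(_LOADERS)


def load_fixture(name: str):
    """Return the typed structure for a packaged fixture.

    Raises :class:`FixtureError` for an unknown name, listing valid ids.
    """
    try:
        loader = _LOADERS[name]
    except KeyError:
        raise FixtureError(
            f"unknown fixture {name!r}; valid ids: {', '.join(FIXTURE_NAMES)}"
        ) from None
    result = loader()
    # hand out copies of mutable containers so callers cannot poison the cache
    if isinstance(result, pd.DataFrame):
        return result.copy()
    if isinstance(result, tuple):
        return tuple(x.copy() for x in result)
    if isinstance(result, dict) and name not in ("table7", "hierarchy"):
        return dict(result)
    return result
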