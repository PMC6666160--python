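"""Ideal-value standardization of representative indexes.

Raw measurements live on incommensurate scales (sensory score, g·sec,
absorbance...).  Each index has an ideal value ``x0`` — the best attainable
value over the reference variety panel: the maximum for a positive index,
the minimum for a negative one, and an interior optimum for a neutral one
(resilience, ideal 0.30).  Standardization proceeds by

* initialization: ``d = |x - x0|`` (distance from the ideal),
* forward-processing + normalization: ``X = 1 - d / D``, where
  ``D = max(|lo - x0|, |hi - x0|)`` is the largest deviation the reference
  range ``[lo, hi]`` allows.

So ``X = 1`` exactly at the ideal, ``X = 0`` at the worst reference
extreme, and ``X`` falls linearly in the distance regardless of the
index's direction.  New samples outside the reference range clamp to
``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from .errors import ValidationError
from . import fixtures
from .schema import PAPER_SCHEMA, REPRESENTATIVE_INDEXES

__all__ = ["IdealEntry", "IdealSpec", "build_ideal_spec", "paper_ideal_spec",
           "standardize", "standardize_table"]


@dataclass(frozen=True)
class IdealEntry:
    name: str
    direction: str       # positive | negative | neutral
    x0: float            # ideal value, index units
    ref_lo: float        # reference panel minimum
    ref_hi: float        # reference panel maximum

    @property
    def D(self) -> float:
        """Maximal possible deviation of the reference range from x0."""
        return max(abs(self.ref_lo - self.x0), abs(self.ref_hi - self.x0))

    def __post_init__(self):
        if self.ref_lo >= self.ref_hi:
            raise ValidationError(f"{self.name}: degenerate reference range")
        if self.direction == "neutral" and not (self.ref_lo < self.x0 < self.ref_hi):
            raise ValidationError(
                f"{self.name}: neutral ideal {self.x0} must lie strictly inside "
                f"[{self.ref_lo}, {self.ref_hi}]"
            )
        if self.D <= 0:
            raise ValidationError(f"{self.name}: zero deviation span")


@dataclass(frozen=True)
class IdealSpec:
    entries: dict  # name -> IdealEntry

    def __getitem__(self, name: str) -> IdealEntry:
        return self.entries[name]

    @property
    def names(self) -> list[str]:
        return list(self.entries)


def build_ideal_spec(
    table2: pd.DataFrame,
    ideals: dict[str, float],
    directions: dict[str, str] | None = None,
) -> IdealSpec:
    """Combine ideal values with reference ranges into a scoring spec.

    ``table2`` supplies per-index ``min``/``max``; *directions* defaults to
    the canonical schema annotation.
    """
    entries = {}
    for name, x0 in ideals.items():
        if name not in table2.index:
            raise ValidationError(f"no reference range for index {name!r}")
        direction = (directions or {}).get(
            name, PAPER_SCHEMA[name].direction if name in PAPER_SCHEMA else "neutral"
        )
        entries[name] = IdealEntry(
            name=name,
            direction=direction,
            x0=float(x0),
            ref_lo=float(table2.at[name, "min"]),
            ref_hi=float(table2.at[name, "max"]),
        )
    return IdealSpec(entries)


def paper_ideal_spec() -> IdealSpec:
    """The shipped reference model: published ideals and panel ranges."""
    return build_ideal_spec(fixtures.load_fixture("table2"),
                            fixtures.load_fixture("table5"))


def standardize(x: float, entry: IdealEntry) -> float:
    """Score a raw value against an ideal entry; result in [0, 1]."""
    if not math.isfinite(x):
        raise ValidationError(f"{entry.name}: non-finite value {x!r}")
    d = abs(x - entry.x0)
    return float(np.clip(1.0 - d / entry.D, 0.0, 1.0))


def standardize_table(
    table: pd.DataFrame,
    spec: IdealSpec | None = None,
    *,
    indexes: list[str] | None = None,
) -> pd.DataFrame:
    """Standardize every representative-index column of *table*.

    Returns a frame of scores X in [0, 1], same row index as the input.
    """
    spec = spec or paper_ideal_spec()
    indexes = indexes or [n for n in REPRESENTATIVE_INDEXES if n in table.columns]
    missing = [n for n in indexes if n not in table.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")
    out = {}
    for name in indexes:
        entry = spec[name]
        out[name] = [standardize(float(v), entry) for v in table[name]]
    return pd.DataFrame(out, index=table.index)
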