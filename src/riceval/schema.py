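"""Canonical index schema for the fresh instant rice quality panel.

Seventeen quality indexes are measured on every variety, grouped into four
categories: CIELAB color values, physicochemical quality, texture-profile
(TPA) characteristics, and panel sensory scores.  Each index carries a
direction: *positive* (larger is better), *negative* (smaller is better) or
*neutral* (an interior ideal value is best).  Directions matter only for the
ideal-value standardization of the five representative indexes; for the
remaining indexes they are descriptive annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "IndexEntry",
    "IndexSchema",
    "PAPER_SCHEMA",
    "REPRESENTATIVE_INDEXES",
    "REPRESENTATIVE_SCHEMA",
    "SchemaError",
]


class SchemaError(ValueError):
    """A table does not conform to the expected index schema."""


CATEGORIES = ("color", "physicochemical", "texture", "sensory")
DIRECTIONS = ("positive", "negative", "neutral")


@dataclass(frozen=True)
class IndexEntry:
    name: str                 # canonical snake_case identifier
    display: str              # human-readable name as printed in reports
    category: str             # one of CATEGORIES
    units: str                # measurement units ("" if dimensionless)
    direction: str            # one of DIRECTIONS

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(f"unknown category {self.category!r} for {self.name}")
        if self.direction not in DIRECTIONS:
            raise SchemaError(f"unknown direction {self.direction!r} for {self.name}")


@dataclass(frozen=True)
class IndexSchema:
    """Ordered collection of index definitions."""

    entries: tuple[IndexEntry, ...]
    _by_name: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise SchemaError("index names must be unique")
        object.__setattr__(self, "_by_name", {e.name: e for e in self.entries})

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> IndexEntry:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(
                f"unknown index {name!r}; expected one of {self.names}"
            ) from None

    def position(self, name: str) -> int:
        """Ordinal position of an index in the schema (tie-break order)."""
        self[name]
        return self.names.index(name)

    def subset(self, names: list[str]) -> "IndexSchema":
        return IndexSchema(tuple(self[n] for n in names))

    def aliases(self) -> dict[str, str]:
        """Map of normalized alternative spellings -> canonical name.

        Covers the canonical identifier, the display name, and a few common
        print variants (e.g. ``b* value``, ``Iodine blue``).
        """
        out: dict[str, str] = {}
        for e in self.entries:
            for alias in (e.name, e.display, *_EXTRA_ALIASES.get(e.name, ())):
                out[_normalize(alias)] = e.name
        return out


def _normalize(label: str) -> str:
    return "".join(ch for ch in label.lower() if ch.isalnum())


_EXTRA_ALIASES = {
    "l_value": ("L*", "L* value", "L value"),
    "a_value": ("a*", "a* value", "a value"),
    "b_value": ("b*", "b* value", "b value"),
    "iodine_color_value": ("iodine blue", "iodine blue value", "iodine"),
    "light_transmittance": ("light transmittance (%)", "transmittance"),
    "gelatinization_degree": ("gelatinization degree (%)",),
    "adhesiveness": ("adhesiveness (g·sec)", "adhesiveness (g.sec)"),
    "hardness": ("hardness (g)",),
    "chewiness": ("chewiness (g)",),
    "sensory_comprehensive_evaluation": (
        "comprehensive evaluation",
        "sensory comprehensive score",
    ),
}


#: The 17-index panel, in the canonical (report) order.
PAPER_SCHEMA = IndexSchema((
    IndexEntry("l_value", "L* value", "color", "", "positive"),
    IndexEntry("a_value", "a* value", "color", "", "neutral"),
    IndexEntry("b_value", "b* value", "color", "", "negative"),
    IndexEntry("iodine_color_value", "Iodine color value", "physicochemical", "", "positive"),
    IndexEntry("light_transmittance", "Light transmittance", "physicochemical", "%", "positive"),
    IndexEntry("gelatinization_degree", "Gelatinization degree", "physicochemical", "%", "positive"),
    IndexEntry("hardness", "Hardness", "texture", "g", "negative"),
    IndexEntry("adhesiveness", "Adhesiveness", "texture", "g·sec", "negative"),
    IndexEntry("springiness", "Springiness", "texture", "", "positive"),
    IndexEntry("cohesiveness", "Cohesiveness", "texture", "", "positive"),
    IndexEntry("chewiness", "Chewiness", "texture", "g", "negative"),
    IndexEntry("resilience", "Resilience", "texture", "", "neutral"),
    IndexEntry("smell", "Smell", "sensory", "score", "positive"),
    IndexEntry("appearance", "Appearance", "sensory", "score", "positive"),
    IndexEntry("palatability", "Palatability", "sensory", "score", "positive"),
    IndexEntry("taste", "Taste", "sensory", "score", "positive"),
    IndexEntry("sensory_comprehensive_evaluation", "Sensory comprehensive evaluation",
               "sensory", "score", "positive"),
))

#: The five representative indexes retained by the screening stage, in the
#: order they enter the evaluation model.
REPRESENTATIVE_INDEXES = [
    "palatability",
    "adhesiveness",
    "resilience",
    "b_value",
    "iodine_color_value",
]

REPRESENTATIVE_SCHEMA = PAPER_SCHEMA.subset(REPRESENTATIVE_INDEXES)
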