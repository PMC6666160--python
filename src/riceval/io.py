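"""Reading and writing variety x index measurement tables.

Tables are plain delimited text (comma by default) with a header row naming
the indexes.  Column names are matched to the schema case-insensitively,
ignoring whitespace, punctuation and the print variants of index names
(``b* value``, ``Iodine blue`` ...).  Unicode minus signs are normalized to
ASCII on parse, since printed tables often carry them.

In memory a table is a :class:`pandas.DataFrame` whose rows are samples
(varieties) and whose columns are canonical index names in schema order.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .schema import PAPER_SCHEMA, IndexSchema

__all__ = ["read_index_table", "write_index_table", "validate_table"]

log = logging.getLogger(__name__)

_UNICODE_MINUS = "−–—"


def _clean_number(raw, row, column) -> float:
    if isinstance(raw, str):
        s = raw.strip()
        for ch in _UNICODE_MINUS:
            s = s.replace(ch, "-")
        if s in ("", "NA", "NaN", "nan"):
            return np.nan
        raw = s
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ParseError(
            f"non-numeric value {raw!r} at row {row!r}, column {column!r}",
            row=row, column=column,
        ) from None


def read_index_table(
    path: str | Path,
    schema: IndexSchema = PAPER_SCHEMA,
    *,
    id_column: str | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Load a variety x index table, validated against *schema*.

    Parameters
    ----------
    path
        Delimited text file with a header row naming indexes.
    schema
        Required indexes; every schema entry must appear as a column.
    id_column
        Column holding sample identifiers.  If ``None``, a column whose
        normalized name is ``sample``, ``variety`` or ``id`` is used when
        present; otherwise rows are numbered.
    sep
        Field delimiter.

    Raises
    ------
    SchemaError
        Missing required column, or an empty file.
    ParseError
        A cell that cannot be parsed as a number (with coordinates).
    """
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, no header row") from None

    aliases = schema.aliases()
    from .schema import _normalize  # shared normalization rule

    id_candidates = {"sample", "samplename", "variety", "id", "name"}
    rename: dict[str, str] = {}
    found_id = None
    for col in raw.columns:
        key = _normalize(str(col))
        if col == id_column or (id_column is None and found_id is None
                                and key in id_candidates):
            found_id = col
        elif key in aliases:
            rename[col] = aliases[key]
        else:
            log.warning("ignoring unknown column %r", col)
    if id_column is not None and found_id is None:
        raise SchemaError(f"id column {id_column!r} not found")

    missing = [e.name for e in schema.entries if e.name not in rename.values()]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = raw.rename(columns=rename)
    if found_id is not None:
        df = df.set_index(found_id)
        df.index.name = "sample"
    df = df[[e.name for e in schema.entries]]

    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        values[col] = [
            _clean_number(v, r, col) for r, v in zip(df.index, df[col])
        ]
    return values


def write_index_table(table: pd.DataFrame, path: str | Path, *, sep: str = ",") -> None:
    """Write a table as delimited text.

    Uses a 17-digit repr so that decimal inputs with up to 6 significant
    digits round-trip bit-exactly through :func:`read_index_table`.
    """
    table.to_csv(path, sep=sep, float_format="%.17g",
                 index_label=table.index.name or "sample")


def validate_table(
    table: pd.DataFrame,
    *,
    min_samples: int = 2,
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Check a table is fit for statistical operations.

    Raises :class:`SchemaError` for too few samples and
    :class:`ValidationError` for missing cells unless *allow_missing*.
    """
    from .errors import ValidationError

    if len(table) < min_samples:
        raise SchemaError(
            f"need at least {min_samples} samples, got {len(table)}"
        )
    if not allow_missing and table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValidationError(f"missing values in column(s): {', '.join(bad)}")
    return table
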