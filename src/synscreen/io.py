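"""Tabular I/O with schema validation.

All stages exchange plain tab-separated text with a one-line header; plate
data has no dominant standard format, so a diffable delimiter-separated
table is the interchange contract.  Each stage's table has a declared
schema (column names, types and row-level checks); reading validates the
header and every row, naming the offending file line on failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .errors import EmptyTableError, MalformedRowError, MissingColumnError

__all__ = [
    "TableSchema",
    "WELLS_SCHEMA",
    "FA_SCHEMA",
    "SERIES_SCHEMA",
    "TRAJECTORY_SCHEMA",
    "read_table",
    "write_table",
]

logger = logging.getLogger(__name__)

SEP = "\t"


@dataclass(frozen=True)
class TableSchema:
    """Column names, pandas dtypes, and row-level validation checks."""

    name: str
    columns: dict[str, str]  # column -> dtype ("str", "float", "int")
    checks: dict[str, Callable[[pd.Series], pd.Series]] = None  # col -> mask of BAD rows

    def __post_init__(self):
        if self.checks is None:
            object.__setattr__(self, "checks", {})


def _bad_nonneg(s: pd.Series) -> pd.Series:
    return s.notna() & (s < 0)


def _bad_nonpos(s: pd.Series) -> pd.Series:
    return s.notna() & (s <= 0)


def _bad_unit_interval(s: pd.Series) -> pd.Series:
    return s.notna() & ((s < 0) | (s > 1))


WELLS_SCHEMA = TableSchema(
    name="wells",
    columns={
        "plate": "str",
        "well": "str",
        "compound_id": "str",
        "arm": "str",
        "dose": "float",
        "replicate": "int",
        "signal": "float",
    },
    checks={"signal": _bad_nonneg, "dose": _bad_nonneg},
)

FA_SCHEMA = TableSchema(
    name="fa",
    columns={
        "compound_id": "str",
        "arm": "str",
        "dose": "float",
        "fa": "float",
        "n": "int",
        "sd": "float",
    },
    checks={"fa": _bad_unit_interval, "sd": _bad_nonneg},
)

SERIES_SCHEMA = TableSchema(
    name="series",
    columns={"drug_id": "str", "dose": "float", "fa": "float"},
    checks={"dose": _bad_nonpos, "fa": _bad_unit_interval},
)

TRAJECTORY_SCHEMA = TableSchema(
    name="trajectories",
    columns={
        "animal_id": "str",
        "group": "str",
        "day": "int",
        "L_mm": "float",
        "S_mm": "float",
    },
    checks={"L_mm": _bad_nonpos, "S_mm": _bad_nonpos, "day": _bad_nonneg},
)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a tab-separated table against ``schema``.

    Raises
    ------
    MissingColumnError
        Header lacks a required column.
    EmptyTableError
        No data rows.
    MalformedRowError
        A value fails type conversion or a row-level check; the message
        names the 1-based file line(s).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=SEP, dtype=str, keep_default_na=False)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"{path.name}: missing column(s) {', '.join(missing)}"
        )
    if df.empty:
        raise EmptyTableError(f"{path.name}: no data rows")

    bad_lines: set[int] = set()
    out = {}
    for col, dtype in schema.columns.items():
        raw = df[col].mask(df[col] == "")
        if dtype == "str":
            out[col] = df[col]
            continue
        vals = pd.to_numeric(raw, errors="coerce")
        unparsable = raw.notna() & vals.isna()
        bad_lines.update(df.index[unparsable] + 2)  # +2: header + 1-based
        if dtype == "int":
            out[col] = vals.astype("Int64")
        else:
            out[col] = vals.astype(float)
    typed = pd.DataFrame(out)
    for col, check in schema.checks.items():
        bad = check(typed[col])
        bad_lines.update(typed.index[bad] + 2)
    if bad_lines:
        shown = ", ".join(str(i) for i in sorted(bad_lines)[:10])
        raise MalformedRowError(
            f"{path.name}: {len(bad_lines)} malformed row(s) at line(s) {shown}"
        )
    logger.info("%s: read %d rows (%s schema)", path.name, len(typed), schema.name)
    return typed


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as tab-separated text with a one-line header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=SEP, index=False, na_rep="")
    return path
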