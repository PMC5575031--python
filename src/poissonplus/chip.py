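"""Chip well tables: schema, validation, CSV round trip.

A chip table holds one record per well of the rectangular array:

=======  =======================================================
column   meaning
=======  =======================================================
row      0-based row index (integer)
col      0-based column index (integer)
rox      ROX passive-reference fluorescence (arbitrary units)
call     amplification call: ``pos``, ``neg`` or ``undet``
=======  =======================================================

Wells with call ``pos`` or ``neg`` are "qualified" and enter quantification;
``undet`` wells (for example unfilled through-holes) are excluded from both
the counts and the ROX statistics.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "CALLS",
    "QUALIFIED_CALLS",
    "REQUIRED_COLUMNS",
    "validate_chip_table",
    "read_chip_table",
    "write_chip_table",
    "qualified_counts",
]

CALLS = ("pos", "neg", "undet")
QUALIFIED_CALLS = ("pos", "neg")
REQUIRED_COLUMNS = ("row", "col", "rox", "call")


def validate_chip_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and dtypes; returns the (possibly coerced) table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"chip table missing columns: {missing}")
    if len(df) == 0:
        raise InvalidInputError("chip table has no wells")
    df = df.copy()
    for col in ("row", "col"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals % 1 != 0).any() or (vals < 0).any():
            raise InvalidInputError(f"column {col!r} must hold non-negative integers")
        df[col] = vals.astype(int)
    rox = pd.to_numeric(df["rox"], errors="coerce")
    if rox.isna().any():
        raise InvalidInputError("column 'rox' must be numeric")
    df["rox"] = rox.astype(float)
    bad = ~df["call"].isin(CALLS)
    if bad.any():
        raise InvalidInputError(
            f"column 'call' must be one of {CALLS}; "
            f"found {sorted(df.loc[bad, 'call'].unique())}"
        )
    return df


def read_chip_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a chip table CSV (header required)."""
    return validate_chip_table(pd.read_csv(path))


def write_chip_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_chip_table(df).to_csv(path, index=False)


def qualified_counts(df: pd.DataFrame):
    """(n_total, n_negative) over qualified wells (call pos or neg)."""
    qualified = df[df["call"].isin(QUALIFIED_CALLS)]
    if len(qualified) == 0:
        raise InvalidInputError("chip has no qualified (pos/neg) wells")
    return len(qualified), int((qualified["call"] == "neg").sum())
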