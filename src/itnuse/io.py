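"""CSV reading/writing with the package's column conventions.

All tables travel as plain CSV.  Keys are opaque text (never numerically
coerced — survey IDs mix zero-padded and alphanumeric forms), nullable
booleans are serialized as 1/0/empty, and reason-code lists as
semicolon-joined strings.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_STR_COLS = ("survey_id", "household_id", "cluster_id", "stratum_id", "member_id")
_BOOL_COLS = (
    "is_itn",
    "used_last_night",
    "defacto",
    "slept_under_itn",
    "uses_nets_year_round",
)
_INT_COLS = ("age_months", "n_users")
_TEXT_FILL = ("raw_reason_codes", "year_round_reasons")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as CSV with nullable booleans encoded as 1/0/empty."""
    out = df.copy()
    for col in out.columns:
        base = col.rsplit("_", 1)[0] if col.rsplit("_", 1)[-1].isdigit() else col
        if base in _BOOL_COLS and out[col].dtype in ("bool", "boolean", object):
            out[col] = out[col].astype("boolean").astype("Int64")
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, restoring dtypes."""
    head = pd.read_csv(path, nrows=0)
    dtype: dict[str, object] = {}
    for col in head.columns:
        base = col.rsplit("_", 1)[0] if col.rsplit("_", 1)[-1].isdigit() else col
        if base in _STR_COLS or col in _STR_COLS:
            dtype[col] = str
        elif base in _BOOL_COLS or base in _INT_COLS:
            dtype[col] = "Int64"
        elif base in _TEXT_FILL:
            dtype[col] = str
    df = pd.read_csv(path, dtype=dtype, keep_default_na=True)
    for col in df.columns:
        base = col.rsplit("_", 1)[0] if col.rsplit("_", 1)[-1].isdigit() else col
        if base in _BOOL_COLS:
            df[col] = df[col].astype("Int64").astype("boolean")
        elif base in _TEXT_FILL:
            df[col] = df[col].fillna("").astype(object)
    return df
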