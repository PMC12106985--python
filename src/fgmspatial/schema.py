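"""Girl-record schema: columns, category levels and validated CSV I/O.

One row per surveyed girl aged 0-14.  Categorical levels are declared in a
fixed order with the reference level first; that order drives both the
reference coding of the design matrix and deterministic modal tie-breaks in
the community aggregates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "CATEGORIES",
    "GIRL_AGE_RANGE",
    "MOTHER_AGE_RANGE",
    "read_records",
    "write_records",
    "validate_records",
    "SchemaError",
]

# Reference level first in every list (the reference rows of the POR table:
# no education, currently married, no-continue, uncut, poorest, Fulani,
# Christian).
CATEGORIES: dict[str, list[str]] = {
    "zone": [
        "north_central",
        "north_east",
        "north_west",
        "south_east",
        "south_south",
        "south_west",
    ],
    "residence": ["urban", "rural"],
    "mother_education": ["none", "primary", "secondary", "higher"],
    "mother_marital": ["current", "former", "never"],
    "ethnicity": [
        "fulani",
        "hausa",
        "ibibio",
        "igbo",
        "ijaw",
        "kanuri",
        "tiv",
        "yoruba",
        "other",
    ],
    "religion": ["christian", "islam", "traditional", "other"],
    "mother_support": ["no", "yes", "dk"],
    "mother_fgm": ["uncut", "cut"],
    "wealth": ["poorest", "poorer", "middle", "richer", "richest"],
    "period": ["pre", "post"],
}

GIRL_AGE_RANGE = (0, 14)
MOTHER_AGE_RANGE = (15, 49)

COLUMNS: list[str] = [
    "girl_id",
    "cluster_id",
    "state_id",
    "zone",
    "residence",
    "girl_age",
    "fgm_status",
    "age_at_cutting",
    "mother_age",
    "mother_education",
    "mother_marital",
    "ethnicity",
    "religion",
    "mother_support",
    "mother_fgm",
    "wealth",
    "weight",
    "period",
]

MISSING = "."


class SchemaError(ValueError):
    """Raised when records violate the girl-record schema."""


def validate_records(df: pd.DataFrame) -> None:
    """Validate a records frame; raise SchemaError listing offending rows.

    Row numbers reported are 1-based data rows (header excluded).
    """
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")
    errors: list[str] = []

    def bad(mask: pd.Series | np.ndarray, msg: str) -> None:
        rows = np.flatnonzero(np.asarray(mask))
        for r in rows[:10]:
            errors.append(f"row {r + 1}: {msg}")
        if len(rows) > 10:
            errors.append(f"... {len(rows) - 10} more rows: {msg}")

    ga = pd.to_numeric(df["girl_age"], errors="coerce")
    bad(
        ~(ga.ge(GIRL_AGE_RANGE[0]) & ga.le(GIRL_AGE_RANGE[1])),
        f"girl_age outside {GIRL_AGE_RANGE}",
    )
    ma = pd.to_numeric(df["mother_age"], errors="coerce")
    bad(
        ~(ma.ge(MOTHER_AGE_RANGE[0]) & ma.le(MOTHER_AGE_RANGE[1])),
        f"mother_age outside {MOTHER_AGE_RANGE}",
    )
    y = pd.to_numeric(df["fgm_status"], errors="coerce")
    bad(~y.isin([0, 1]), "fgm_status not in {0, 1}")
    w = pd.to_numeric(df["weight"], errors="coerce")
    bad(~w.gt(0), "weight not positive")
    for col, levels in CATEGORIES.items():
        bad(~df[col].astype(str).isin(levels), f"{col} not in {levels}")
    aac = pd.to_numeric(df["age_at_cutting"], errors="coerce")
    cut = y == 1
    bad(cut & aac.isna(), "age_at_cutting missing for a cut girl")
    bad(~cut & aac.notna(), "age_at_cutting present for an uncut girl")
    bad(cut & aac.notna() & (aac > ga), "age_at_cutting exceeds girl_age")
    if errors:
        raise SchemaError("; ".join(errors))


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("girl_age", "fgm_status", "mother_age"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    df["age_at_cutting"] = pd.to_numeric(df["age_at_cutting"], errors="coerce")
    df["weight"] = pd.to_numeric(df["weight"]).astype(float)
    for col in ("girl_id", "cluster_id", "state_id"):
        df[col] = df[col].astype(str)
    for col in CATEGORIES:
        df[col] = df[col].astype(str)
    return df


def read_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a girl-records CSV ('.' marks missing values)."""
    df = pd.read_csv(path, dtype=str, na_values=[MISSING], keep_default_na=False)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing mandatory columns: {missing_cols}")
    df = df[COLUMNS]
    df = _coerce(df)
    validate_records(df)
    return df


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Write records to CSV with the fixed column order and '.' for missing."""
    validate_records(df)
    out = df[COLUMNS].copy()
    aac = out["age_at_cutting"]
    out["age_at_cutting"] = np.where(
        aac.notna(), aac.fillna(0).astype(float).astype(int).astype(str), MISSING
    )
    out["weight"] = out["weight"].map(lambda v: format(float(v), ".10g"))
    out.to_csv(path, index=False, lineterminator="\n")
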