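"""Cohort table reading, validation and writing.

The cohort CSV is the pipeline's sole input: one row per individual with
gender, age, family-history label and the six body measurements in natural
units.  The genotype column is optional — simulated cohorts carry it as
ground truth, real data never has it, and the analysis never reads it.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MEASURE_COLUMNS

__all__ = ["COHORT_COLUMNS", "read_cohort", "write_cohort"]

COHORT_COLUMNS = ("id", "gender", "age", "fh") + MEASURE_COLUMNS

# Plausible adult ranges used only for warnings, never rejection.
_RANGE_HEURISTICS = {
    "age": (10.0, 100.0),
    "height_m": (1.2, 2.2),
    "waist_cm": (40.0, 200.0),
    "hip_cm": (50.0, 200.0),
    "lean_kg": (20.0, 100.0),
    "bone_kg": (1.0, 6.0),
    "fat_kg": (1.0, 100.0),
}


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises a named error on missing columns, missing values or non-numeric
    measurements; out-of-range values only warn (units may legitimately
    differ in edge populations).
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing column(s): {missing}")
    numeric = ("age",) + MEASURE_COLUMNS
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column {col!r} is not numeric: {exc}") from exc
    na_cols = [c for c in COHORT_COLUMNS if df[c].isna().any()]
    if na_cols:
        raise ValueError(f"missing values in column(s): {na_cols}")
    for col in ("gender", "fh"):
        levels = set(df[col].unique())
        expected = {"F", "M"} if col == "gender" else {"FH+", "FH-"}
        if not levels <= expected:
            raise ValueError(
                f"column {col!r} has unexpected label(s): {sorted(levels - expected)}"
            )
    for col in MEASURE_COLUMNS:
        if (df[col] <= 0).any():
            row = df.index[df[col] <= 0][0]
            raise ValueError(f"non-positive measurement in column {col!r}, row {row}")
    for col, (lo, hi) in _RANGE_HEURISTICS.items():
        bad = (df[col] < lo) | (df[col] > hi)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} value(s) in {col!r} outside plausible range "
                f"[{lo}, {hi}] — check units"
            )
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as plain CSV with the fixed header."""
    cols = [c for c in ("id", "gender", "age", "fh", "genotype") if c in cohort.columns]
    cols += list(MEASURE_COLUMNS)
    cohort[cols].to_csv(path, index=False)
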