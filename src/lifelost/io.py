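"""Schema-validated CSV input/output.

Dialects
--------
* Patient CSV: ``id, t, died, age_dx, year_dx[, h_star, covariates...]``;
  times in fractional years since diagnosis.
* Comparator CSV: ``id, age_entry, age_exit, died, year_match[, covariates]``;
  ages in fractional years.
* Rate-table CSV ("popmort" dialect): ``age, year, rate`` with rates in
  events per person-year.  Life tables published as annual death
  probabilities can be read with ``dialect="prob"`` (column ``prob``), which
  converts via rate = −ln(1 − p).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .population import RateTable

__all__ = [
    "read_patients",
    "read_comparators",
    "read_rate_table",
    "write_rate_table",
]


def _require_columns(df: pd.DataFrame, required, what: str, problems: list):
    missing = set(required) - set(df.columns)
    for c in sorted(missing):
        problems.append(f"{what}: missing required column '{c}'")
    return not missing


def _require_numeric(df: pd.DataFrame, cols, what: str, problems: list):
    ok = True
    for c in cols:
        if c not in df.columns:
            continue
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[vals.isna() & df[c].notna()]
        if len(bad):
            problems.append(f"{what}: non-numeric values in '{c}' at rows {list(bad[:5])}")
            ok = False
        df[c] = vals
    return ok


def read_patients(path) -> pd.DataFrame:
    """Load and validate a patient CSV (optionally with a merged h_star column)."""
    df = pd.read_csv(path)
    problems: list[str] = []
    if _require_columns(df, ["t", "died", "age_dx", "year_dx"], "patients", problems):
        if _require_numeric(df, ["t", "died", "age_dx", "year_dx", "h_star"],
                            "patients", problems):
            bad_t = df.index[df["t"] <= 0]
            if len(bad_t):
                problems.append(f"patients: non-positive follow-up time at rows {list(bad_t[:5])}")
            bad_d = df.index[~df["died"].isin([0, 1])]
            if len(bad_d):
                problems.append(f"patients: died not in {{0,1}} at rows {list(bad_d[:5])}")
            bad_a = df.index[df["age_dx"] <= 0]
            if len(bad_a):
                problems.append(f"patients: non-positive age_dx at rows {list(bad_a[:5])}")
            if "h_star" in df.columns and (df["h_star"] < 0).any():
                problems.append("patients: negative h_star values")
    if problems:
        raise SchemaError(problems)
    return df


def read_comparators(path) -> pd.DataFrame:
    """Load and validate a comparator CSV."""
    df = pd.read_csv(path)
    problems: list[str] = []
    if _require_columns(df, ["age_entry", "age_exit", "died", "year_match"],
                        "comparators", problems):
        if _require_numeric(df, ["age_entry", "age_exit", "died", "year_match"],
                            "comparators", problems):
            bad = df.index[df["age_exit"] <= df["age_entry"]]
            if len(bad):
                problems.append(
                    f"comparators: age_exit <= age_entry at rows {list(bad[:5])}")
            bad_d = df.index[~df["died"].isin([0, 1])]
            if len(bad_d):
                problems.append(f"comparators: died not in {{0,1}} at rows {list(bad_d[:5])}")
            bad_a = df.index[df["age_entry"] <= 0]
            if len(bad_a):
                problems.append(f"comparators: non-positive age_entry at rows {list(bad_a[:5])}")
    if problems:
        raise SchemaError(problems)
    return df


def read_rate_table(path, dialect: str = "rate") -> RateTable:
    """Load a popmort-style life table.

    ``dialect="rate"`` expects a ``rate`` column (events per person-year);
    ``dialect="prob"`` expects annual death probabilities in a ``prob``
    column and converts with rate = −ln(1 − p).
    """
    df = pd.read_csv(path)
    problems: list[str] = []
    value_col = {"rate": "rate", "prob": "prob"}.get(dialect)
    if value_col is None:
        raise SchemaError([f"rate table: unknown dialect '{dialect}'"])
    if _require_columns(df, ["age", "year", value_col], "rate table", problems):
        _require_numeric(df, ["age", "year", value_col], "rate table", problems)
        if not problems:
            if dialect == "prob":
                if ((df["prob"] < 0) | (df["prob"] >= 1)).any():
                    problems.append("rate table: probabilities must lie in [0, 1)")
                else:
                    df = df.assign(rate=-np.log1p(-df["prob"]))
            if "rate" in df.columns and (df["rate"] < 0).any():
                problems.append("rate table: negative rates")
    if problems:
        raise SchemaError(problems)
    return RateTable.from_frame(df[["age", "year", "rate"]])


def write_rate_table(table: RateTable, path) -> None:
    table.to_frame().to_csv(path, index=False)
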