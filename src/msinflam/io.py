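"""Cohort table reading/writing with schema validation."""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .panel import panel_map
from .synthetic import DIAGNOSES, SEVERITY_COLS

log = logging.getLogger(__name__)

REQUIRED = ("subject_id", "diagnosis")
NA_VALUES = ["", "NA", "NaN", "nan"]


class SchemaError(ValueError):
    pass


def read_cohort(path) -> pd.DataFrame:
    """Read a long-format visit table (CSV or TSV by extension).

    Requires ``subject_id``, ``diagnosis`` and either ``visit_index`` or a
    parseable ``visit_date`` (ranked per subject into a visit index).
    Empty strings and "NA" parse as missing; diagnosis values must be one
    of HD/RRMS/PPMS/SPMS.  Logs a schema report.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, na_values=NA_VALUES, keep_default_na=True)
    for col in REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if "visit_index" not in df.columns:
        if "visit_date" not in df.columns:
            raise SchemaError("missing required column 'visit_index' (or 'visit_date')")
        dates = pd.to_datetime(df["visit_date"], errors="raise")
        df["visit_index"] = dates.groupby(df["subject_id"]).rank(method="first").astype(int)
    bad = ~df["diagnosis"].astype(str).isin(DIAGNOSES)
    if bad.any():
        rows = df.index[bad].tolist()
        vals = sorted(set(df.loc[bad, "diagnosis"].astype(str)))
        raise SchemaError(f"unknown diagnosis values {vals} in rows {rows[:10]}")
    pm = panel_map()
    numeric = [c for c in df.columns if c in pm or c in SEVERITY_COLS or c == "age"]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    n_subjects = df["subject_id"].nunique()
    miss = df.isna().mean()
    log.info("cohort %s: %d rows, %d subjects; missingness per column: %s",
             path.name, len(df), n_subjects,
             {c: round(float(miss[c]), 3) for c in df.columns if miss[c] > 0})
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)
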