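"""Readers and writers for the four source tables and pipeline outputs.

The source tables emulate a CPRD/HES extract: a patient register, a therapy
(prescribing) file, a coded clinical-event file with free-text terms, and
hospital inpatient episodes with a primary ICD-10 diagnosis. Files are
delimited text; column names are configurable through :class:`Schema` so a
real extract can be mapped without code changes. Rows failing validation
are collected into a rejects table with a reason, never silently dropped.

Dates are ISO-8601 in files and ``datetime64[ns]`` (day resolution)
internally; every interval in the package is half-open ``[start, end)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

DRUG_CLASSES = frozenset({"ICS", "SABA", "prednisolone", "LABA", "LTRA", "other"})
GENDERS = frozenset({"male", "female"})

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.?\d{1,2})?$")


@dataclass(frozen=True)
class Schema:
    """Column-name mapping for the four input tables.

    Defaults mirror CPRD field naming (``patid``, ``eventdate``, ``qty``...).
    Keys are the package's logical names; values the file's header names.
    """

    delimiter: str = ","
    date_format: str = "%Y-%m-%d"
    patient: dict = field(default_factory=lambda: {
        "patient_id": "patid",
        "gender": "gender",
        "birth_date": "birthdate",
        "index_date": "indexdate",
        "exit_date": "exitdate",
        "copd_flag": "copd",
    })
    therapy: dict = field(default_factory=lambda: {
        "patient_id": "patid",
        "drug_class": "drugclass",
        "issue_date": "eventdate",
        "quantity_packs": "qty",
        "doses_per_pack": "packdoses",
        "daily_dose": "dailydose",
        "strength": "strength",
        "duration_days": "duration",
        "dosage_form": "form",
    })
    clinical: dict = field(default_factory=lambda: {
        "patient_id": "patid",
        "event_date": "eventdate",
        "term_text": "term",
    })
    hes: dict = field(default_factory=lambda: {
        "patient_id": "patid",
        "admission_date": "admidate",
        "primary_icd10": "icdprimary",
    })

    def with_delimiter(self, delimiter: str) -> "Schema":
        return replace(self, delimiter=delimiter)


class Cohort(NamedTuple):
    patients: pd.DataFrame
    therapy: pd.DataFrame
    clinical: pd.DataFrame
    episodes: pd.DataFrame
    rejects: pd.DataFrame


def _raw_read(path, schema: Schema, colmap: dict) -> pd.DataFrame:
    df = pd.read_csv(path, sep=schema.delimiter, dtype=str, keep_default_na=False)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = df[[colmap[k] for k in colmap]].copy()
    out.columns = list(colmap)
    return out


def _parse_date(series: pd.Series, fmt: str) -> pd.Series:
    s = series.str.strip()
    out = pd.to_datetime(s, format=fmt, errors="coerce")
    out[s == ""] = pd.NaT
    return out


def _parse_num(series: pd.Series) -> pd.Series:
    s = series.str.strip()
    out = pd.to_numeric(s, errors="coerce")
    out[s == ""] = np.nan
    return out


def _finish(df: pd.DataFrame, keep: pd.Series, reason: pd.Series, table: str):
    rej = pd.DataFrame({
        "table": table,
        "row": np.flatnonzero(~keep.to_numpy()) + 1,  # 1-based data rows
        "reason": reason[~keep].to_numpy(),
    })
    return df[keep].reset_index(drop=True), rej


def read_patients(path, schema: Schema | None = None):
    schema = schema or Schema()
    df = _raw_read(path, schema, schema.patient)
    reason = pd.Series("", index=df.index)
    for col in ("birth_date", "index_date", "exit_date"):
        raw = df[col]
        df[col] = _parse_date(raw, schema.date_format)
        bad = df[col].isna()
        reason[bad & (reason == "")] = f"bad date in {col}"
    df["gender"] = df["gender"].str.strip().str.lower()
    bad = ~df["gender"].isin(GENDERS)
    reason[bad & (reason == "")] = "unknown gender"
    df["copd_flag"] = df["copd_flag"].str.strip().str.lower().isin({"1", "true", "yes"})
    order = df["index_date"] > df["exit_date"]
    reason[order.fillna(False) & (reason == "")] = "index_date after exit_date"
    return _finish(df, reason == "", reason, "patient")


def read_therapy(path, schema: Schema | None = None):
    schema = schema or Schema()
    df = _raw_read(path, schema, schema.therapy)
    reason = pd.Series("", index=df.index)
    df["issue_date"] = _parse_date(df["issue_date"], schema.date_format)
    reason[df["issue_date"].isna() & (reason == "")] = "bad date"
    df["drug_class"] = df["drug_class"].str.strip()
    reason[~df["drug_class"].isin(DRUG_CLASSES) & (reason == "")] = "unknown drug_class"
    for col in ("quantity_packs", "doses_per_pack", "daily_dose", "strength", "duration_days"):
        raw = df[col]
        df[col] = _parse_num(raw)
        garbled = df[col].isna() & (raw.str.strip() != "")
        reason[garbled & (reason == "")] = f"unparseable {col}"
    neg = df["quantity_packs"] < 0
    reason[neg.fillna(False) & (reason == "")] = "negative quantity"
    badd = df["duration_days"] < 1
    reason[badd.fillna(False) & (reason == "")] = "nonpositive duration"
    df["dosage_form"] = df["dosage_form"].str.strip()
    return _finish(df, reason == "", reason, "therapy")


def read_clinical(path, schema: Schema | None = None):
    schema = schema or Schema()
    df = _raw_read(path, schema, schema.clinical)
    reason = pd.Series("", index=df.index)
    df["event_date"] = _parse_date(df["event_date"], schema.date_format)
    reason[df["event_date"].isna() & (reason == "")] = "bad date"
    empty = df["term_text"].str.strip() == ""
    reason[empty & (reason == "")] = "empty term"
    return _finish(df, reason == "", reason, "clinical")


def read_hes(path, schema: Schema | None = None):
    schema = schema or Schema()
    df = _raw_read(path, schema, schema.hes)
    reason = pd.Series("", index=df.index)
    df["admission_date"] = _parse_date(df["admission_date"], schema.date_format)
    reason[df["admission_date"].isna() & (reason == "")] = "bad date"
    code = df["primary_icd10"].str.strip().str.upper()
    df["primary_icd10"] = code
    bad = ~code.map(lambda c: bool(_ICD10_RE.match(c)))
    reason[bad & (reason == "")] = "malformed ICD-10 code"
    return _finish(df, reason == "", reason, "hes")


def read_cohort(patient_path, therapy_path, clinical_path, hes_path,
                schema: Schema | None = None) -> Cohort:
    """Read and validate the four source tables.

    Returns validated frames plus one combined rejects frame
    (``table``, ``row``, ``reason``); accepted + rejected row counts always
    equal the input row counts.
    """
    schema = schema or Schema()
    patients, r1 = read_patients(patient_path, schema)
    therapy, r2 = read_therapy(therapy_path, schema)
    clinical, r3 = read_clinical(clinical_path, schema)
    episodes, r4 = read_hes(hes_path, schema)
    rejects = pd.concat([r1, r2, r3, r4], ignore_index=True)
    return Cohort(patients, therapy, clinical, episodes, rejects)


def write_patient_year_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a patient-year table sorted by (patient_id, t), 6 dp floats."""
    out = df.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep=delimiter, index=False, float_format="%.6f")


def read_patient_year_table(path, delimiter: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter)


def write_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df.to_csv(path, sep=delimiter, index=False, float_format="%.6f")
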