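"""Readers and writers for the three registry tables.

Input files are delimited text (comma by default, tab accepted), UTF-8, with
ISO-8601 dates. Multi-valued code columns (procedure and diagnosis codes)
are packed into one field joined by a configurable delimiter (default ``;``).

Rows violating record invariants are not silently dropped: every reader
returns ``(table, rejections)`` where the rejection report carries the input
row number (0-based, excluding the header) and a reason. A missing required
column is a file-level :class:`SchemaError` instead.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .codelists import ATC_PATTERN

__all__ = [
    "SchemaError",
    "read_consultations", "read_dispensings", "read_population",
    "write_consultations", "write_dispensings", "write_population",
    "CONSULTATION_COLUMNS", "DISPENSING_COLUMNS", "PERSON_COLUMNS",
]

CONSULTATION_COLUMNS = ["patient_id", "date", "service_type", "mode_codes", "diagnosis_codes"]
DISPENSING_COLUMNS = ["patient_id", "date", "atc_code"]
PERSON_COLUMNS = ["patient_id", "birth_date", "sex", "death_date",
                  "residency_start", "residency_end"]


class SchemaError(ValueError):
    """The file is structurally unusable (e.g. a required column is absent)."""


def _read_raw(path: str, required: list[str], sep: Optional[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, engine="python" if sep is None else "c",
                     keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def _parse_date(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")


def _reject(report: list, idx: np.ndarray, reason: str) -> None:
    report.extend((int(i), reason) for i in idx)


def _finalize(df: pd.DataFrame, bad: pd.Series, report: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    rejections = pd.DataFrame(report, columns=["row", "reason"]).sort_values("row",
                                                                             kind="stable")
    return df.loc[~bad].reset_index(drop=True), rejections.reset_index(drop=True)


def read_consultations(path: str, sep: Optional[str] = ",",
                       code_delim: str = ";") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the consultation table; returns ``(consultations, rejections)``.

    Output columns: patient_id, date (datetime), service_type ('DGP'/'OOH'),
    mode_codes, diagnosis_codes (delimiter-joined strings).
    """
    df = _read_raw(path, CONSULTATION_COLUMNS, sep)
    report: list = []
    n = len(df)
    bad = pd.Series(False, index=df.index)

    dates = _parse_date(df["date"])
    m = dates.isna()
    _reject(report, df.index[m & ~bad], "bad date")
    bad |= m

    service = df["service_type"].str.strip().str.upper()
    m = ~service.isin(["DGP", "OOH"])
    _reject(report, df.index[m & ~bad], "bad service_type")
    bad |= m

    diag = df["diagnosis_codes"].str.strip()
    m = diag == ""
    _reject(report, df.index[m & ~bad], "empty diagnosis_codes")
    bad |= m

    out = pd.DataFrame({
        "patient_id": df["patient_id"],
        "date": dates,
        "service_type": service,
        "mode_codes": df["mode_codes"].str.strip(),
        "diagnosis_codes": diag,
    })
    out.attrs["code_delim"] = code_delim
    table, rejections = _finalize(out, bad, report)
    assert len(table) + len(rejections) == n
    return table, rejections


def read_dispensings(path: str, sep: Optional[str] = ",") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the dispensing table; returns ``(dispensings, rejections)``."""
    df = _read_raw(path, DISPENSING_COLUMNS, sep)
    report: list = []
    bad = pd.Series(False, index=df.index)

    dates = _parse_date(df["date"])
    m = dates.isna()
    _reject(report, df.index[m & ~bad], "bad date")
    bad |= m

    atc = df["atc_code"].str.strip().str.upper()
    m = ~atc.str.fullmatch(ATC_PATTERN.pattern)
    _reject(report, df.index[m & ~bad], "bad atc_code")
    bad |= m

    out = pd.DataFrame({"patient_id": df["patient_id"], "date": dates, "atc_code": atc})
    return _finalize(out, bad, report)


def read_population(path: str, sep: Optional[str] = ",") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the person table; returns ``(persons, rejections)``.

    One demographic row per person; a duplicated patient_id is a file-level
    error. death_date and residency_end may be empty (open).
    """
    df = _read_raw(path, ["patient_id", "birth_date", "sex"], sep)
    for optional in ("death_date", "residency_start", "residency_end"):
        if optional not in df.columns:
            df[optional] = ""
    dup = df["patient_id"].duplicated()
    if dup.any():
        raise SchemaError(
            f"duplicate patient_id(s): {sorted(df.loc[dup, 'patient_id'].unique())[:5]}")

    report: list = []
    bad = pd.Series(False, index=df.index)

    birth = _parse_date(df["birth_date"])
    m = birth.isna()
    _reject(report, df.index[m & ~bad], "bad birth_date")
    bad |= m

    sex = df["sex"].str.strip().str.lower()
    m = ~sex.isin(["male", "female"])
    _reject(report, df.index[m & ~bad], "bad sex")
    bad |= m

    death = _parse_date(df["death_date"].replace("", pd.NA))
    m = df["death_date"].str.strip().ne("") & death.isna()
    _reject(report, df.index[m & ~bad], "bad death_date")
    bad |= m
    m = death.notna() & (death < birth)
    _reject(report, df.index[m & ~bad], "death before birth")
    bad |= m

    res_start = _parse_date(df["residency_start"].replace("", pd.NA))
    res_end = _parse_date(df["residency_end"].replace("", pd.NA))
    m = res_start.notna() & res_end.notna() & (res_end < res_start)
    _reject(report, df.index[m & ~bad], "residency_end before residency_start")
    bad |= m

    out = pd.DataFrame({
        "patient_id": df["patient_id"],
        "birth_date": birth,
        "sex": sex,
        "death_date": death,
        "residency_start": res_start,
        "residency_end": res_end,
    })
    return _finalize(out, bad, report)


def _fmt_dates(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d").fillna("")
    return out


def write_consultations(df: pd.DataFrame, path: str, sep: str = ",") -> None:
    _fmt_dates(df[CONSULTATION_COLUMNS], ["date"]).to_csv(path, sep=sep, index=False)


def write_dispensings(df: pd.DataFrame, path: str, sep: str = ",") -> None:
    _fmt_dates(df[DISPENSING_COLUMNS], ["date"]).to_csv(path, sep=sep, index=False)


def write_population(df: pd.DataFrame, path: str, sep: str = ",") -> None:
    cols = ["birth_date", "death_date", "residency_start", "residency_end"]
    _fmt_dates(df[PERSON_COLUMNS], cols).to_csv(path, sep=sep, index=False)
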