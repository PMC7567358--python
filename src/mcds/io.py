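"""Reading, validating and writing the tabular inputs of the score pipeline.

All files are delimited text (comma by default, tab via ``sep="\t"``) with a
header row, UTF-8, ISO-8601 dates.  The expected schemas are:

claims
    ``patient_id, atc_code, dispense_date[, n_packages]``
cohort
    ``patient_id, age_at_index, sex, index_date`` (``age_at_index`` may be
    replaced by ``birth_year``, in which case age is computed at the index
    date)
outcomes
    ``patient_id[, death_date][, hospitalization_date]``

Column names can be remapped with a ``schema`` dict (``{file column name:
canonical name}`` inverse mapping, i.e. ``{"canonical": "actual"}``).

Validation is row-level: malformed rows are rejected, reported with their
line numbers and the reason, and reading continues unless ``strict=True``.
Window filtering is deliberately *not* applied at read time; the condition
mapper owns the lookback window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "RejectedRow",
    "ReadReport",
    "read_prescriptions",
    "read_cohort",
    "read_outcomes",
    "write_table",
    "build_survival",
    "ATC_FULL_RE",
    "is_valid_atc",
]


class SchemaError(ValueError):
    """A mandatory column is missing or the file cannot be parsed at all."""


class ValidationError(ValueError):
    """Row-level invariant violation in strict mode, or an invalid cross-file link."""


# ATC structural pattern by code length: 1 letter / +2 digits / +1 letter /
# +1 letter / +2 digits.  Valid prefixes have length 1, 3, 4, 5 or 7.
ATC_FULL_RE = re.compile(r"^[A-Z]$|^[A-Z]\d{2}$|^[A-Z]\d{2}[A-Z]$|^[A-Z]\d{2}[A-Z]{2}$|^[A-Z]\d{2}[A-Z]{2}\d{2}$")


def is_valid_atc(code: str) -> bool:
    """True iff *code* is structurally valid at some level of the ATC hierarchy."""
    return bool(ATC_FULL_RE.match(code))


@dataclass(frozen=True)
class RejectedRow:
    line_number: int
    reason: str


@dataclass
class ReadReport:
    """What happened while reading a file: kept rows and rejections."""

    n_read: int = 0
    rejected: list[RejectedRow] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_read - len(self.rejected)


def _resolve_columns(df: pd.DataFrame, required: list[str], optional: list[str],
                     schema: dict[str, str] | None) -> pd.DataFrame:
    schema = schema or {}
    rename = {actual: canon for canon, actual in schema.items() if actual in df.columns}
    df = df.rename(columns=rename)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r} (have: {list(df.columns)})")
    keep = required + [c for c in optional if c in df.columns]
    return df[keep]


def _parse_dates(s: pd.Series) -> pd.Series:
    # ISO-8601 only; anything else becomes NaT and is rejected by the caller.
    return pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")


def read_prescriptions(path, schema: dict[str, str] | None = None, *,
                       sep: str = ",", strict: bool = False
                       ) -> tuple[pd.DataFrame, ReadReport]:
    """Read a pharmacy-claims file into a validated prescription table.

    Returns ``(claims, report)`` where *claims* has columns ``patient_id``
    (str), ``atc_code`` (uppercase str), ``dispense_date`` (datetime64) and
    ``n_packages`` (int, 1 where the column is absent), and *report* lists
    rejected rows with 1-based data line numbers.
    """
    df = pd.read_csv(path, sep=sep, dtype={0: str}, keep_default_na=False)
    df = _resolve_columns(df, ["patient_id", "atc_code", "dispense_date"], ["n_packages"], schema)
    report = ReadReport(n_read=len(df))

    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["atc_code"] = df["atc_code"].astype(str).str.strip().str.upper()
    dates = _parse_dates(df["dispense_date"])

    bad_atc = ~df["atc_code"].map(is_valid_atc)
    bad_date = dates.isna()
    if "n_packages" in df.columns:
        npk = pd.to_numeric(df["n_packages"], errors="coerce")
        bad_pkg = npk.isna() | (npk <= 0) | (npk != npk.round())
    else:
        npk = pd.Series(1, index=df.index)
        bad_pkg = pd.Series(False, index=df.index)

    for idx in df.index[bad_atc]:
        report.rejected.append(RejectedRow(
            idx + 1,
            f"atc_code {df.at[idx, 'atc_code']!r} does not match the ATC structural "
            "pattern (letter, 2 digits, 2 letters, 2 digits, or a prefix thereof)"))
    for idx in df.index[bad_date & ~bad_atc]:
        report.rejected.append(RejectedRow(idx + 1, f"dispense_date {df.at[idx, 'dispense_date']!r} is not a valid ISO-8601 date"))
    for idx in df.index[bad_pkg & ~bad_atc & ~bad_date]:
        report.rejected.append(RejectedRow(idx + 1, f"n_packages {df.at[idx, 'n_packages']!r} is not a positive integer"))

    if strict and report.rejected:
        first = report.rejected[0]
        raise ValidationError(f"line {first.line_number}: {first.reason}")

    keep = ~(bad_atc | bad_date | bad_pkg)
    out = df.loc[keep, ["patient_id", "atc_code"]].copy()
    out["dispense_date"] = dates[keep]
    out["n_packages"] = npk[keep].astype(int)
    return out.reset_index(drop=True), report


def read_cohort(path, schema: dict[str, str] | None = None, *, sep: str = ",",
                min_age: int | None = 50) -> pd.DataFrame:
    """Read a cohort file: one row per patient with age, sex and index date.

    ``birth_year`` is accepted in place of ``age_at_index``.  With the
    default eligibility filter (``min_age=50``) younger patients raise a
    :class:`ValidationError`; pass ``min_age=None`` to disable the filter.
    """
    df = pd.read_csv(path, sep=sep, dtype={0: str}, keep_default_na=False)
    schema = schema or {}
    rename = {actual: canon for canon, actual in schema.items() if actual in df.columns}
    df = df.rename(columns=rename)
    for col in ("patient_id", "sex", "index_date"):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["index_date"] = _parse_dates(df["index_date"])
    if df["index_date"].isna().any():
        raise ValidationError("unparseable index_date (ISO-8601 required)")
    if "age_at_index" in df.columns:
        df["age_at_index"] = pd.to_numeric(df["age_at_index"]).astype(int)
    elif "birth_year" in df.columns:
        df["age_at_index"] = df["index_date"].dt.year - pd.to_numeric(df["birth_year"]).astype(int)
    else:
        raise SchemaError("need either 'age_at_index' or 'birth_year'")
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    bad_sex = ~df["sex"].isin(["female", "male", "f", "m"])
    if bad_sex.any():
        raise ValidationError(f"unrecognized sex values: {sorted(df.loc[bad_sex, 'sex'].unique())}")
    df["sex"] = df["sex"].str[0].map({"f": "female", "m": "male"})
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"duplicate patient_id in cohort file: {dup!r}")
    if min_age is not None and (df["age_at_index"] < min_age).any():
        n = int((df["age_at_index"] < min_age).sum())
        raise ValidationError(f"{n} patients below the eligibility age of {min_age}")
    return df[["patient_id", "age_at_index", "sex", "index_date"]].reset_index(drop=True)


def read_outcomes(path, schema: dict[str, str] | None = None, *, sep: str = ",") -> pd.DataFrame:
    """Read an outcomes file: death and/or first-hospitalization dates.

    Missing dates are NaT; a patient may appear with neither outcome.
    """
    df = pd.read_csv(path, sep=sep, dtype={0: str}, keep_default_na=False)
    df = _resolve_columns(df, ["patient_id"], ["death_date", "hospitalization_date"], schema)
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for col in ("death_date", "hospitalization_date"):
        if col in df.columns:
            raw = df[col].astype(str).str.strip()
            parsed = _parse_dates(raw.replace("", pd.NA))
            if (parsed.isna() & (raw != "")).any():
                raise ValidationError(f"unparseable {col} (ISO-8601 or blank required)")
            df[col] = parsed
        else:
            df[col] = pd.NaT
    return df[["patient_id", "death_date", "hospitalization_date"]].reset_index(drop=True)


def write_table(df: pd.DataFrame, path, *, sep: str = ",") -> None:
    """Write any of the pipeline tables back to delimited text (dates as ISO-8601)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=sep, index=False)


def build_survival(cohort: pd.DataFrame, outcomes: pd.DataFrame,
                   follow_up_days: int = 365, *, event_col: str = "death_date"
                   ) -> pd.DataFrame:
    """Turn cohort + outcome dates into (time, event) survival records.

    An event within ``(index_date, index_date + follow_up_days]`` gives
    ``event=1`` and ``time`` in days from index; otherwise the patient is
    administratively censored at ``follow_up_days``.  ``event_col`` may be
    ``"hospitalization_date"`` for the secondary outcome; the machinery is
    identical.
    """
    if follow_up_days <= 0:
        raise ValueError("follow_up_days must be positive")
    unknown = set(outcomes["patient_id"]) - set(cohort["patient_id"])
    if unknown:
        raise ValidationError(f"outcome rows for patients absent from the cohort: {sorted(unknown)[:5]}")
    merged = cohort[["patient_id", "index_date"]].merge(
        outcomes[["patient_id", event_col]], on="patient_id", how="left")
    days = (merged[event_col] - merged["index_date"]).dt.days
    if (days <= 0).any():
        bad = merged.loc[days <= 0, "patient_id"].iloc[0]
        raise ValidationError(
            f"{event_col} on or before index_date for patient {bad!r}; the cohort is alive at index")
    event = days.notna() & (days <= follow_up_days)
    time = np.where(event, days, follow_up_days)
    return pd.DataFrame({
        "patient_id": merged["patient_id"],
        "time": time.astype(int),
        "event": event.astype(int),
    })
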