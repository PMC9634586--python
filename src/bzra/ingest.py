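"""Reading, validating and year-scoping of prescription dispensing records.

Exclusion is two-tier, mirroring how dispensing-database studies treat bad
rows versus bad demographics:

* *hard* exclusion removes a record from every analysis — unknown drug,
  unparseable or out-of-year visit date, non-positive dose or duration,
  missing identifiers;
* *soft* exclusion keeps the patient in descriptive outputs (with an
  ``unknown`` category) but drops them from the regression — missing gender,
  age or diagnosis information.

Coverage of a record is the closed calendar interval
``[visit_date, visit_date + days_supplied - 1]``; supplies overrunning
Dec 31 of the study year are truncated to the year end.
"""

from __future__ import annotations

import calendar
import datetime as dt
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import CSV_COLUMNS, PrescriptionRecord
from .registry import DMETable

__all__ = ["CleanCohort", "SchemaError", "read_prescriptions", "truncate_to_year",
           "truncate_frame"]

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Input file does not carry the documented column set."""


@dataclass
class CleanCohort:
    """Validated records plus the exclusion ledger."""

    records: pd.DataFrame
    study_year: int
    excluded_count: int = 0
    exclusion_reasons: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.excluded_count != sum(self.exclusion_reasons.values()):
            raise ValueError("excluded_count must equal the sum of exclusion_reasons")

    @property
    def n_patients(self) -> int:
        return self.records["patient_id"].nunique()

    @property
    def soft_excluded_patients(self) -> set[str]:
        """Patients with missing gender, age or diagnoses anywhere in their records.

        These stay in descriptive outputs but are dropped from the regression.
        """
        rec = self.records
        bad = (
            (rec["gender"] == "unknown")
            | rec["age_years"].isna()
            | (rec["diagnoses"].fillna("") == "")
        )
        return set(rec.loc[bad, "patient_id"])


def truncate_to_year(record: PrescriptionRecord, year: int) -> PrescriptionRecord:
    """Clamp a record's supply so coverage ends no later than Dec 31 of `year`.

    Idempotent; requires the visit date to lie inside the year.
    """
    if record.visit_date.year != year:
        raise ValueError(
            f"visit_date {record.visit_date} outside study year {year}"
        )
    year_end = dt.date(year, 12, 31)
    max_days = (year_end - record.visit_date).days + 1
    if record.days_supplied <= max_days:
        return record
    return PrescriptionRecord(
        **{**record.__dict__, "days_supplied": max_days}
    )


def truncate_frame(records: pd.DataFrame, year: int) -> pd.DataFrame:
    """Vectorised :func:`truncate_to_year` over a record DataFrame."""
    out = records.copy()
    year_end = pd.Timestamp(dt.date(year, 12, 31))
    max_days = (year_end - pd.to_datetime(out["visit_date"])).dt.days + 1
    if (max_days < 1).any():
        raise ValueError(f"records with visit_date outside study year {year}")
    out["days_supplied"] = out["days_supplied"].clip(upper=max_days).astype(int)
    return out


def read_prescriptions(
    path: str | Path,
    registry: DMETable,
    year: int | None = None,
) -> CleanCohort:
    """Read a prescription CSV into a validated, year-scoped :class:`CleanCohort`.

    Parameters
    ----------
    path : CSV file in the documented dialect (columns :data:`~bzra.records.CSV_COLUMNS`).
    registry : drug table defining which drug identifiers are in scope.
    year : study year; defaults to the modal visit year of the file.

    Raises
    ------
    SchemaError : when a required column is absent.
    """
    path = Path(path)
    raw = pd.read_csv(
        path,
        dtype={
            "patient_id": str, "hospital_id": str, "doctor_id": str,
            "visit_date": str, "drug_id": str, "diagnoses": str, "gender": str,
        },
    )
    missing_cols = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required column(s) {missing_cols}")
    if raw.empty:
        log.warning("%s: empty prescription file", path)
        return CleanCohort(records=raw.assign(visit_date=pd.NaT), study_year=year or 0)

    reasons = Counter()
    keep = pd.Series(True, index=raw.index)

    def _exclude(mask: pd.Series, reason: str) -> None:
        mask = mask & keep
        if mask.any():
            reasons[reason] += int(mask.sum())
            keep[mask] = False

    dates = pd.to_datetime(raw["visit_date"], format="%Y-%m-%d", errors="coerce")
    _exclude(dates.isna(), "unparseable_date")
    if year is None:
        year = int(dates.dt.year.mode().iloc[0])

    _exclude(dates.dt.year != year, "outside_study_year")
    _exclude(~raw["drug_id"].isin(registry.specs), "unknown_drug")
    dose = pd.to_numeric(raw["daily_dose_mg"], errors="coerce")
    _exclude(dose.isna() | (dose <= 0), "nonpositive_dose")
    days = pd.to_numeric(raw["days_supplied"], errors="coerce")
    _exclude(days.isna() | (days <= 0), "nonpositive_duration")
    _exclude(raw["patient_id"].isna() | (raw["patient_id"] == ""), "missing_patient_id")

    rec = raw[keep].copy()
    rec["visit_date"] = dates[keep]
    rec["daily_dose_mg"] = dose[keep].astype(float)
    rec["days_supplied"] = days[keep].astype(int)
    rec["age_years"] = pd.to_numeric(rec["age_years"], errors="coerce")
    rec["gender"] = rec["gender"].fillna("unknown").replace("", "unknown")
    rec["diagnoses"] = rec["diagnoses"].fillna("")

    # truncate coverage at Dec 31 of the study year
    rec = truncate_frame(rec, year)

    # multi-hospital patients are assigned the hospital of their first dispensing
    first = rec.sort_values(["visit_date", "hospital_id"]).groupby("patient_id")["hospital_id"].first()
    rec["hospital_id"] = rec["patient_id"].map(first)

    return CleanCohort(
        records=rec.reset_index(drop=True),
        study_year=year,
        excluded_count=sum(reasons.values()),
        exclusion_reasons=reasons,
    )
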