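"""Prescription dispensing records and their CSV representation.

One :class:`PrescriptionRecord` is a single out-patient dispensing event: who
(patient, with demographics), where (hospital, prescribing doctor), when
(visit date), which drug, at what daily dose (mg) and for how many days, under
which ICD-10 diagnoses.  Records are exchanged on disk as plain CSV with the
fixed column set :data:`CSV_COLUMNS`; diagnoses are semicolon-joined, dates
ISO-8601, and missing gender/age/diagnoses are empty fields.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = ["PrescriptionRecord", "CSV_COLUMNS", "write_records_csv", "read_records_csv",
           "records_to_frame", "frame_to_records"]

CSV_COLUMNS = [
    "patient_id",
    "hospital_id",
    "doctor_id",
    "visit_date",
    "drug_id",
    "daily_dose_mg",
    "days_supplied",
    "diagnoses",
    "gender",
    "age_years",
]

GENDERS = ("female", "male", "unknown")


@dataclass
class PrescriptionRecord:
    patient_id: str
    hospital_id: str
    doctor_id: str
    visit_date: dt.date
    drug_id: str
    daily_dose_mg: float
    days_supplied: int
    diagnoses: list[str] = field(default_factory=list)
    gender: str = "unknown"
    age_years: int | None = None

    @property
    def end_date(self) -> dt.date:
        """Last covered calendar day: the interval [visit_date, end_date] is closed."""
        return self.visit_date + dt.timedelta(days=self.days_supplied - 1)


def _format_row(rec: PrescriptionRecord) -> list[str]:
    return [
        rec.patient_id,
        rec.hospital_id,
        rec.doctor_id,
        rec.visit_date.isoformat(),
        rec.drug_id,
        repr(rec.daily_dose_mg),
        str(rec.days_supplied),
        ";".join(rec.diagnoses),
        "" if rec.gender == "unknown" else rec.gender,
        "" if rec.age_years is None else str(rec.age_years),
    ]


def write_records_csv(records: Iterable[PrescriptionRecord], path: str | Path) -> int:
    """Write records to CSV; returns the number of rows written.

    The float daily dose is written with ``repr`` so the write → read
    round-trip is lossless.
    """
    path = Path(path)
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            n = 0
            for rec in records:
                writer.writerow(_format_row(rec))
                n += 1
    except OSError as exc:
        raise OSError(f"cannot write prescription CSV at {path}: {exc}") from exc
    return n


def read_records_csv(path: str | Path) -> Iterator[PrescriptionRecord]:
    """Yield records from a CSV written by :func:`write_records_csv`.

    This is the strict inverse of the writer; tolerant, validating ingest
    lives in :mod:`bzra.ingest`.
    """
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            yield PrescriptionRecord(
                patient_id=row["patient_id"],
                hospital_id=row["hospital_id"],
                doctor_id=row["doctor_id"],
                visit_date=dt.date.fromisoformat(row["visit_date"]),
                drug_id=row["drug_id"],
                daily_dose_mg=float(row["daily_dose_mg"]),
                days_supplied=int(row["days_supplied"]),
                diagnoses=[c for c in row["diagnoses"].split(";") if c],
                gender=row["gender"] or "unknown",
                age_years=int(row["age_years"]) if row["age_years"] else None,
            )


def records_to_frame(records: Iterable[PrescriptionRecord]) -> pd.DataFrame:
    """Tabulate records into the canonical analysis DataFrame."""
    rows = [
        {
            "patient_id": r.patient_id,
            "hospital_id": r.hospital_id,
            "doctor_id": r.doctor_id,
            "visit_date": pd.Timestamp(r.visit_date),
            "drug_id": r.drug_id,
            "daily_dose_mg": r.daily_dose_mg,
            "days_supplied": r.days_supplied,
            "diagnoses": ";".join(r.diagnoses),
            "gender": r.gender,
            "age_years": float("nan") if r.age_years is None else float(r.age_years),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[PrescriptionRecord]:
    out = []
    for row in frame.itertuples(index=False):
        age = getattr(row, "age_years")
        out.append(
            PrescriptionRecord(
                patient_id=row.patient_id,
                hospital_id=row.hospital_id,
                doctor_id=row.doctor_id,
                visit_date=pd.Timestamp(row.visit_date).date(),
                drug_id=row.drug_id,
                daily_dose_mg=float(row.daily_dose_mg),
                days_supplied=int(row.days_supplied),
                diagnoses=[c for c in str(row.diagnoses).split(";") if c],
                gender=row.gender,
                age_years=None if pd.isna(age) else int(age),
            )
        )
    return out
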