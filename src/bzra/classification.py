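"""Rule-based usage labels: overdose, long-term, hazardous, over-indication.

The rules operate on the per-patient exposure statistics:

* **overdose** — maximum 90-day-window average daily dose strictly above
  40 DME/day;
* **long-term** — longest gap-bridged continuous-use episode of at least 90
  days (inclusive cutoff: three back-to-back 30-day prescriptions qualify,
  consistent with the 30-day prescription-length ceiling that motivates the
  cutoff);
* **hazardous** — the conjunction of the two, always;
* **over-indication** — none of the patient's recorded diagnoses over the
  whole study year prefix-matches any approved indication of any drug
  dispensed to them.  Diagnoses are pooled across visits, not matched
  visit-by-visit.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exposure import ExposureMetrics
from .registry import IndicationMap

__all__ = [
    "Thresholds",
    "HazardLabel",
    "flag_overdose",
    "flag_long_term",
    "flag_hazardous",
    "flag_over_indication",
    "per_drug_over_indication",
    "label_cohort",
]


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds, recorded alongside every labelling run."""

    dme_threshold: float = 40.0
    day_threshold: int = 90
    max_gap: int = 3
    window_days: int = 90


@dataclass(frozen=True)
class HazardLabel:
    patient_id: str
    overdose: bool
    long_term: bool
    hazardous: bool
    over_indication: bool | None
    thresholds: Thresholds = Thresholds()

    def __post_init__(self) -> None:
        if self.hazardous != (self.overdose and self.long_term):
            raise ValueError("hazardous must equal overdose AND long_term")


def flag_overdose(metrics: ExposureMetrics, dme_threshold: float = 40.0) -> bool:
    """Overdose use: window-maximum average daily dose strictly above the threshold."""
    return metrics.max_window_avg_dme > dme_threshold


def flag_long_term(metrics: ExposureMetrics, day_threshold: int = 90) -> bool:
    """Long-term use: longest bridged episode reaches the cutoff (inclusive)."""
    return metrics.max_continuous_days >= day_threshold


def flag_hazardous(
    metrics: ExposureMetrics,
    thresholds: Thresholds = Thresholds(),
    over_indication: bool | None = None,
) -> HazardLabel:
    """Hazardous use is the conjunction of overdose and long-term use."""
    overdose = flag_overdose(metrics, thresholds.dme_threshold)
    long_term = flag_long_term(metrics, thresholds.day_threshold)
    return HazardLabel(
        patient_id=metrics.patient_id,
        overdose=overdose,
        long_term=long_term,
        hazardous=overdose and long_term,
        over_indication=over_indication,
        thresholds=thresholds,
    )


def _patient_diagnoses(patient_records: pd.DataFrame) -> set[str]:
    codes: set[str] = set()
    for cell in patient_records["diagnoses"]:
        codes.update(c.strip().upper() for c in str(cell).split(";") if c.strip())
    return codes


def per_drug_over_indication(
    patient_records: pd.DataFrame, indications: IndicationMap
) -> dict[str, bool]:
    """Per dispensed drug: is the drug unjustified by every pooled diagnosis?

    Powers the drug-level over-indication ranking; the patient-level flag is
    the conjunction over dispensed drugs.
    """
    codes = _patient_diagnoses(patient_records)
    flags: dict[str, bool] = {}
    for drug in sorted(set(patient_records["drug_id"])):
        flags[drug] = not any(indications.matches(drug, c) for c in codes)
    return flags


def flag_over_indication(
    patient_records: pd.DataFrame, indications: IndicationMap
) -> bool:
    """Patient-level rule: no pooled diagnosis justifies any dispensed drug."""
    if not _patient_diagnoses(patient_records):
        raise ValueError(
            "over-indication flag undefined for a patient without diagnoses "
            "(soft-excluded upstream)"
        )
    return all(per_drug_over_indication(patient_records, indications).values())


def label_cohort(
    metrics: pd.DataFrame,
    records: pd.DataFrame,
    indications: IndicationMap,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Label every patient; one row per patient.

    ``over_indication`` is left missing (``pd.NA``) for patients without any
    recorded diagnosis — they stay out of the over-indication denominators.
    """
    by_patient = dict(tuple(records.groupby("patient_id", sort=False)))
    rows = []
    for row in metrics.itertuples(index=False):
        overdose = row.max_window_avg_dme > thresholds.dme_threshold
        long_term = row.max_continuous_days >= thresholds.day_threshold
        prec = by_patient[row.patient_id]
        if _patient_diagnoses(prec):
            over_ind = flag_over_indication(prec, indications)
        else:
            over_ind = pd.NA
        rows.append(
            {
                "patient_id": row.patient_id,
                "hospital_id": row.hospital_id,
                "overdose": overdose,
                "long_term": long_term,
                "hazardous": overdose and long_term,
                "over_indication": over_ind,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["patient_id", "hospital_id", "overdose", "long_term", "hazardous", "over_indication"],
    )
    out.attrs["thresholds"] = thresholds
    return out
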