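"""Per-patient daily dose arrays and exposure statistics.

The central object is the *daily dose array*: for each patient, a vector with
one entry per calendar day of the study year holding the total dispensed dose
attributable to that day, expressed in diazepam milligram equivalents (DME).
Each dispensing contributes its daily DME to every day of its closed coverage
interval; doses of overlapping dispensings stack (sum) on shared days, which
is why dose intensity is judged by the *maximum 90-day window average* rather
than by any single day — a patient stockpiling three months of supply in one
visit is averaged back out over the window.

From the array, six per-patient statistics are derived:

* maximum windowed average daily DME (90-day sliding window, calendar-day
  denominator),
* total yearly DME,
* maximum days of continuous use, where gaps of up to ``max_gap`` (default 3)
  non-use days do not interrupt an episode and bridged gap days count toward
  the episode's calendar span,
* total days of use (days with any dispensed dose),
* number of out-patient visits (distinct date x doctor dispensing events),
* number of distinct doctors visited.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import DMETable

__all__ = [
    "DailyDoseArray",
    "ExposureMetrics",
    "build_daily_array",
    "max_window_average",
    "detect_max_run",
    "compute_metrics",
    "compute_cohort_metrics",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "max_window_avg_dme",
    "total_dme",
    "max_continuous_days",
    "total_days_of_use",
    "n_visits",
    "n_distinct_doctors",
    "average_daily_dme",
]


def year_length(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


@dataclass
class DailyDoseArray:
    """Per-patient daily DME vector; index 0 is Jan 1 of `year`."""

    patient_id: str
    year: int
    dme_by_day: np.ndarray

    def __post_init__(self) -> None:
        self.dme_by_day = np.asarray(self.dme_by_day, dtype=float)
        if len(self.dme_by_day) != year_length(self.year):
            raise ValueError(
                f"array length {len(self.dme_by_day)} does not match year {self.year}"
            )


@dataclass
class ExposureMetrics:
    patient_id: str
    max_window_avg_dme: float
    total_dme: float
    max_continuous_days: int
    total_days_of_use: int
    n_visits: int
    n_distinct_doctors: int
    average_daily_dme: float


def build_daily_array(
    records: pd.DataFrame, registry: DMETable, year: int
) -> DailyDoseArray:
    """Accumulate one patient's truncated dispensings into a daily DME array.

    Every record adds ``to_dme(drug, daily_dose_mg)`` to each day of its
    coverage interval; overlapping records sum.  Records must already be
    scoped and truncated to `year`.
    """
    n = year_length(year)
    arr = np.zeros(n)
    if len(records) == 0:
        return DailyDoseArray(patient_id="", year=year, dme_by_day=arr)
    pids = records["patient_id"].unique()
    if len(pids) > 1:
        raise ValueError(f"records belong to several patients: {sorted(pids)[:3]}...")
    jan1 = pd.Timestamp(year=year, month=1, day=1)
    for row in records.itertuples(index=False):
        start = (pd.Timestamp(row.visit_date) - jan1).days
        length = int(row.days_supplied)
        if start < 0 or start + length > n:
            raise ValueError(
                f"record of {row.patient_id} at {row.visit_date} (+{length}d) "
                f"falls outside year {year}; truncate first"
            )
        arr[start : start + length] += registry.to_dme(row.drug_id, float(row.daily_dose_mg))
    return DailyDoseArray(patient_id=str(pids[0]), year=year, dme_by_day=arr)


def _as_vector(array: DailyDoseArray | np.ndarray) -> np.ndarray:
    if isinstance(array, DailyDoseArray):
        return array.dme_by_day
    return np.asarray(array, dtype=float)


def max_window_average(array: DailyDoseArray | np.ndarray, window_days: int = 90) -> float:
    """Largest mean daily DME over any contiguous `window_days`-day window.

    Days without use count as zeros in the denominator (calendar-day
    denominator).  Ties resolve to the earliest window.
    """
    vec = _as_vector(array)
    if window_days < 1:
        raise ValueError("window_days must be at least 1")
    if window_days > len(vec):
        raise ValueError(
            f"window_days {window_days} exceeds array length {len(vec)}"
        )
    csum = np.concatenate([[0.0], np.cumsum(vec)])
    sums = csum[window_days:] - csum[:-window_days]
    return float(sums.max() / window_days)


def detect_max_run(array: DailyDoseArray | np.ndarray, max_gap: int = 3) -> int:
    """Longest continuous-use episode in days, bridging gaps of up to `max_gap`.

    Use-runs separated by at most `max_gap` consecutive non-use days merge
    into one episode; the returned length is the episode's calendar span from
    first to last use day inclusive (bridged gap days count).  Returns 0 for
    a patient with no use days.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    use_days = np.flatnonzero(_as_vector(array) > 0)
    if use_days.size == 0:
        return 0
    best = 0
    run_start = prev = int(use_days[0])
    for day in use_days[1:]:
        day = int(day)
        if day - prev - 1 > max_gap:
            best = max(best, prev - run_start + 1)
            run_start = day
        prev = day
    return max(best, prev - run_start + 1)


def compute_metrics(
    records: pd.DataFrame,
    registry: DMETable,
    year: int,
    window_days: int = 90,
    max_gap: int = 3,
) -> ExposureMetrics:
    """Assemble all exposure statistics for one patient."""
    if len(records) == 0:
        raise ValueError("cannot compute exposure metrics for an empty record set")
    array = build_daily_array(records, registry, year)
    vec = array.dme_by_day
    total_dme = float(vec.sum())
    total_days = int((vec > 0).sum())
    n_visits = len(records[["visit_date", "doctor_id"]].drop_duplicates())
    return ExposureMetrics(
        patient_id=array.patient_id,
        max_window_avg_dme=max_window_average(array, window_days),
        total_dme=total_dme,
        max_continuous_days=detect_max_run(array, max_gap),
        total_days_of_use=total_days,
        n_visits=n_visits,
        n_distinct_doctors=records["doctor_id"].nunique(),
        average_daily_dme=total_dme / total_days if total_days else 0.0,
    )


def compute_cohort_metrics(
    records: pd.DataFrame,
    registry: DMETable,
    year: int,
    window_days: int = 90,
    max_gap: int = 3,
) -> pd.DataFrame:
    """Exposure metrics for every patient, one row per patient.

    The returned frame carries the seven metric columns plus ``patient_id``
    and ``hospital_id`` (the patient's assigned hospital).
    """
    rows = []
    for pid, group in records.groupby("patient_id", sort=True):
        m = compute_metrics(group, registry, year, window_days, max_gap)
        rows.append(
            {
                "patient_id": pid,
                "hospital_id": group["hospital_id"].iloc[0],
                "max_window_avg_dme": m.max_window_avg_dme,
                "total_dme": m.total_dme,
                "max_continuous_days": m.max_continuous_days,
                "total_days_of_use": m.total_days_of_use,
                "n_visits": m.n_visits,
                "n_distinct_doctors": m.n_distinct_doctors,
                "average_daily_dme": m.average_daily_dme,
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "hospital_id", *METRIC_COLUMNS])
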