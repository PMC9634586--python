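"""Cohort-level descriptive and comparative statistics.

Produces the standard reporting surface for a dispensing-database study of
hypnotic use: demographics, diagnosis-block distributions, per-hospital
medians with interquartile ranges for the exposure metrics, hazardous and
over-indication prevalence, drug-class usage (benzodiazepines only, Z-drugs
only, both), DDD consumption, per-drug usage by hazard group, and the
ranking of drugs most often dispensed over-indication.

Group comparisons use the classical tests matched to the data type:
chi-square for categorical variables (Yates continuity correction on 2x2
tables by default), the Wilcoxon rank-sum test for a continuous variable
across two groups, Kruskal-Wallis across three or more.

Quartiles use the linear-interpolation definition (numpy default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .registry import DMETable, DrugClass

__all__ = [
    "AGE_GROUPS",
    "DIAGNOSIS_BLOCKS",
    "GroupTestResult",
    "age_group",
    "diagnosis_blocks_of",
    "classify_drug_use",
    "ddd_consumption",
    "compare_groups",
    "over_indication_report",
    "summarize_cohort",
    "render_report_markdown",
]

AGE_GROUPS = ("<18", "18-64", ">=65")

#: reporting blocks for ICD-10 mental/behavioural and sleep/epilepsy chapters
DIAGNOSIS_BLOCKS: list[tuple[str, str, int, int]] = [
    ("F01-F09", "F", 1, 9),
    ("F10-F19", "F", 10, 19),
    ("F20-F29", "F", 20, 29),
    ("F30-F39", "F", 30, 39),
    ("F40-F49", "F", 40, 49),
    ("F50-F59", "F", 50, 59),
    ("F60-F69", "F", 60, 69),
    ("F70-F79", "F", 70, 79),
    ("F80-F89", "F", 80, 89),
    ("F90-F98", "F", 90, 98),
    ("F99", "F", 99, 99),
    ("G40-G41", "G", 40, 41),
    ("G47", "G", 47, 47),
]

_CODE_RE = re.compile(r"^([A-Z])([0-9]{1,2})")


def age_group(age: float | None) -> str:
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return "unknown"
    if age < 18:
        return "<18"
    if age < 65:
        return "18-64"
    return ">=65"


def diagnosis_blocks_of(code: str) -> list[str]:
    """Reporting blocks containing an ICD-10 code (usually one, possibly none)."""
    m = _CODE_RE.match(code.strip().upper())
    if not m:
        return []
    letter, num = m.group(1), int(m.group(2))
    return [name for name, blk_letter, lo, hi in DIAGNOSIS_BLOCKS
            if letter == blk_letter and lo <= num <= hi]


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    test_name: str
    group_sizes: tuple[int, ...]


def classify_drug_use(drug_ids, registry: DMETable) -> str:
    """Classify a patient's year of dispensing as BZD_only / Z_only / both."""
    classes = {registry.drug_class(d) for d in set(drug_ids)}
    if not classes:
        raise ValueError("patient has no dispensed drugs")
    if classes == {DrugClass.BZD}:
        return "BZD_only"
    if classes == {DrugClass.Z_DRUG}:
        return "Z_only"
    return "both"


def ddd_consumption(
    records: pd.DataFrame,
    registry: DMETable,
    by: tuple[str, ...] = ("hospital_id", "drug_class"),
) -> pd.Series:
    """Total defined daily doses dispensed, grouped.

    Each record contributes ``(daily_dose_mg * days_supplied) / ddd_mg`` of
    its drug.  `by` may name any record columns plus the derived
    ``drug_class``.
    """
    rec = records.copy()
    rec["drug_class"] = [registry.drug_class(d).value for d in rec["drug_id"]]
    rec["ddd"] = [
        registry.to_ddd(d, dose * days)
        for d, dose, days in zip(rec["drug_id"], rec["daily_dose_mg"], rec["days_supplied"])
    ]
    if not by:
        return rec["ddd"].sum()
    return rec.groupby(list(by), sort=True)["ddd"].sum()


def compare_groups(
    values: pd.Series,
    groups: pd.Series,
    kind: str = "auto",
    yates_2x2: bool = True,
) -> GroupTestResult:
    """Classical two-or-more-group comparison, test chosen by data type.

    Categorical values → chi-square on the contingency table; continuous
    values → Wilcoxon rank-sum (two groups) or Kruskal-Wallis (three or
    more).
    """
    values, groups = pd.Series(values).reset_index(drop=True), pd.Series(groups).reset_index(drop=True)
    levels = [g for g, n in groups.value_counts().items() if n > 0]
    if len(levels) < 2:
        raise ValueError("need at least two non-empty groups")
    sizes = tuple(int((groups == g).sum()) for g in sorted(map(str, levels)))

    categorical = kind == "chi_square" or (
        kind == "auto" and (values.dtype == object or values.dtype == bool
                            or isinstance(values.dtype, pd.CategoricalDtype))
    )
    if categorical:
        table = pd.crosstab(values, groups)
        correction = yates_2x2 and table.shape == (2, 2)
        chi2, p, _, _ = stats.chi2_contingency(table.values, correction=correction)
        return GroupTestResult(float(chi2), float(p), "chi_square", sizes)

    samples = [values[groups == g].astype(float).to_numpy() for g in sorted(map(str, levels))]
    if len(samples) == 2 and kind in ("auto", "wilcoxon_rank"):
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return GroupTestResult(float(stat), float(p), "wilcoxon_rank", sizes)
    stat, p = stats.kruskal(*samples)
    return GroupTestResult(float(stat), float(p), "kruskal_wallis", sizes)


def _median_iqr(x: pd.Series) -> dict[str, float]:
    arr = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def _proportions(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: (100.0 * v / total if total else 0.0) for k, v in counts.items()}


def over_indication_report(
    records: pd.DataFrame,
    labels: pd.DataFrame,
    per_drug_flags: pd.DataFrame,
) -> pd.DataFrame:
    """Rank drugs by their share of over-indication patients.

    `per_drug_flags` has columns patient_id, drug_id, over_indication (the
    per-drug rule).  For each drug the report gives the percentage of
    over-indication patients dispensed it over-indication, and the diagnosis
    blocks recorded for those patients.
    """
    over_pids = set(labels.loc[labels["over_indication"] == True, "patient_id"])  # noqa: E712
    if not over_pids:
        return pd.DataFrame(columns=["drug_id", "pct_of_over_indication_patients", "top_blocks"])
    flagged = per_drug_flags[
        per_drug_flags["patient_id"].isin(over_pids) & per_drug_flags["over_indication"]
    ]
    dx_by_patient: dict[str, set[str]] = {}
    for pid, group in records[records["patient_id"].isin(over_pids)].groupby("patient_id"):
        codes = set()
        for cell in group["diagnoses"]:
            codes.update(c for c in str(cell).split(";") if c)
        dx_by_patient[pid] = codes

    rows = []
    for drug, group in flagged.groupby("drug_id"):
        pids = set(group["patient_id"])
        block_counts: dict[str, int] = {}
        for pid in pids:
            blocks = set()
            for code in dx_by_patient.get(pid, ()):  # blocks of offending diagnoses
                blocks.update(diagnosis_blocks_of(code))
            for b in blocks:
                block_counts[b] = block_counts.get(b, 0) + 1
        top = sorted(block_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
        rows.append(
            {
                "drug_id": drug,
                "pct_of_over_indication_patients": 100.0 * len(pids) / len(over_pids),
                "top_blocks": [
                    {"block": b, "pct": 100.0 * c / len(pids)} for b, c in top
                ],
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "pct_of_over_indication_patients", ascending=False, ignore_index=True
    )
    return out


def summarize_cohort(
    metrics: pd.DataFrame,
    labels: pd.DataFrame,
    records: pd.DataFrame,
    registry: DMETable,
    n_total_outpatients: int | None = None,
) -> dict[str, Any]:
    """Assemble the full cohort report as one nested plain-data structure.

    A pure function of its inputs: identical inputs yield an identical
    report.  Proportions are percentages; exposure metrics are summarised as
    median with interquartile range, overall and per hospital.
    """
    n = len(metrics)
    if n == 0:
        raise ValueError("empty cohort")

    per_patient = records.groupby("patient_id").agg(
        gender=("gender", "first"), age_years=("age_years", "first")
    )
    per_patient["age_group"] = [age_group(a) for a in per_patient["age_years"]]
    gender_counts = per_patient["gender"].value_counts().to_dict()
    age_counts = per_patient["age_group"].value_counts().to_dict()

    # diagnosis blocks: a patient counts once in every block touched
    block_counts = {name: 0 for name, *_ in DIAGNOSIS_BLOCKS}
    for _, group in records.groupby("patient_id"):
        blocks: set[str] = set()
        for cell in group["diagnoses"]:
            for code in str(cell).split(";"):
                if code:
                    blocks.update(diagnosis_blocks_of(code))
        for b in blocks:
            block_counts[b] += 1

    drug_use = (
        records.groupby("patient_id")["drug_id"]
        .apply(lambda ds: classify_drug_use(ds, registry))
        .value_counts()
        .to_dict()
    )
    for key in ("BZD_only", "Z_only", "both"):
        drug_use.setdefault(key, 0)

    merged = metrics.merge(labels[["patient_id", "overdose", "long_term", "hazardous", "over_indication"]],
                           on="patient_id")
    haz_count = int(merged["hazardous"].sum())
    over_known = merged["over_indication"].dropna()

    metric_cols = [
        "max_window_avg_dme", "total_dme", "max_continuous_days",
        "total_days_of_use", "n_visits", "n_distinct_doctors",
    ]
    per_hospital = {}
    for hosp, group in merged.groupby("hospital_id"):
        per_hospital[str(hosp)] = {
            "n_patients": int(len(group)),
            "hazardous_pct": 100.0 * float(group["hazardous"].mean()),
            "metrics": {c: _median_iqr(group[c]) for c in metric_cols},
        }

    # per-drug usage percentage by hazard group
    patient_drugs = records.groupby("patient_id")["drug_id"].apply(set)
    haz_pids = set(merged.loc[merged["hazardous"], "patient_id"])
    usage_by_group: dict[str, dict[str, float]] = {"hazardous": {}, "non_hazardous": {}}
    n_haz, n_non = len(haz_pids), n - len(haz_pids)
    for drug in registry.drug_ids:
        users = patient_drugs[patient_drugs.apply(lambda s: drug in s)].index
        in_haz = sum(1 for p in users if p in haz_pids)
        usage_by_group["hazardous"][drug] = 100.0 * in_haz / n_haz if n_haz else 0.0
        usage_by_group["non_hazardous"][drug] = (
            100.0 * (len(users) - in_haz) / n_non if n_non else 0.0
        )

    ddd_class = ddd_consumption(records, registry, by=("hospital_id", "drug_class"))
    ddd_drug = ddd_consumption(records, registry, by=("hospital_id", "drug_id"))

    report: dict[str, Any] = {
        "n_bzra_patients": n,
        "n_total_outpatients": n_total_outpatients,
        "bzra_prevalence_pct": (
            100.0 * n / n_total_outpatients if n_total_outpatients else None
        ),
        "demographics": {
            "gender_pct": _proportions(gender_counts),
            "age_group_pct": _proportions(age_counts),
        },
        "diagnosis_block_pct": {b: 100.0 * c / n for b, c in block_counts.items()},
        "metrics_overall": {c: _median_iqr(merged[c]) for c in metric_cols},
        "per_hospital": per_hospital,
        "hazardous": {
            "count": haz_count,
            "pct": 100.0 * haz_count / n,
            "overdose_pct": 100.0 * float(merged["overdose"].mean()),
            "long_term_pct": 100.0 * float(merged["long_term"].mean()),
        },
        "over_indication": {
            "count": int(over_known.sum()),
            "pct": 100.0 * float(over_known.mean()) if len(over_known) else None,
            "n_assessable": int(len(over_known)),
        },
        "drug_class_use_pct": _proportions(drug_use),
        "ddd_by_hospital_class": {
            f"{h}|{c}": float(v) for (h, c), v in ddd_class.items()
        },
        "ddd_by_hospital_drug": {
            f"{h}|{d}": float(v) for (h, d), v in ddd_drug.items()
        },
        "drug_usage_pct_by_hazard_group": usage_by_group,
    }
    return report


def render_report_markdown(report: dict[str, Any]) -> str:
    """Plain-text rendering of the cohort report (table-style sections)."""
    lines = ["# Cohort report", ""]
    lines.append(f"Patients on BZRAs: {report['n_bzra_patients']}")
    if report.get("bzra_prevalence_pct") is not None:
        lines.append(
            f"BZRA prevalence among out-patients: {report['bzra_prevalence_pct']:.1f}%"
        )
    lines += ["", "## Demographics"]
    for section in ("gender_pct", "age_group_pct"):
        for k, v in report["demographics"][section].items():
            lines.append(f"- {k}: {v:.1f}%")
    lines += ["", "## Exposure metrics (median [IQR])"]
    for name, d in report["metrics_overall"].items():
        lines.append(f"- {name}: {d['median']:.1f} [{d['q1']:.1f}-{d['q3']:.1f}]")
    hz = report["hazardous"]
    lines += [
        "",
        "## Hazardous use",
        f"- hazardous: {hz['count']} ({hz['pct']:.1f}%)",
        f"- overdose: {hz['overdose_pct']:.1f}%",
        f"- long-term: {hz['long_term_pct']:.1f}%",
    ]
    oi = report["over_indication"]
    if oi["pct"] is not None:
        lines.append(f"- over-indication: {oi['count']} ({oi['pct']:.1f}%)")
    lines += ["", "## Drug-class use"]
    for k, v in report["drug_class_use_pct"].items():
        lines.append(f"- {k}: {v:.1f}%")
    lines += ["", "## Per-hospital hazardous prevalence"]
    for h, d in sorted(report["per_hospital"].items()):
        lines.append(f"- {h}: n={d['n_patients']}, hazardous {d['hazardous_pct']:.1f}%")
    return "\n".join(lines) + "\n"
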