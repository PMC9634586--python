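"""End-to-end orchestration: simulate → ingest → exposure → classify → report → regress.

Every run is reproducible: outputs land in one directory together with a log
recording the seed, the configuration hash, the classification thresholds and
the regression family.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .classification import Thresholds, label_cohort, per_drug_over_indication
from .cohort_stats import age_group, over_indication_report, render_report_markdown, summarize_cohort
from .exposure import compute_cohort_metrics
from .ingest import read_prescriptions
from .registry import load_registry
from .regression import build_design, fit_multilevel
from .synthetic import CohortConfig, generate_cohort, hospital_regions, write_cohort

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


class RunConfig(BaseModel):
    """One pipeline run: either an input CSV or a simulation config, plus knobs."""

    input_csv: Path | None = None
    simulate: CohortConfig | None = None
    out_dir: Path
    registry_path: Path | None = None
    dme_threshold: float = Field(default=40.0, gt=0)
    day_threshold: int = Field(default=90, gt=0)
    max_gap: int = Field(default=3, ge=0)
    window_days: int = Field(default=90, gt=0)
    family: str = "linear_probability"
    seed: int = 0
    n_total_outpatients: int | None = None
    region_map: dict[str, str] | None = None


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the in-memory results keyed by stage.

    Writes ``prescriptions.csv`` (when simulating), ``metrics.csv``,
    ``labels.csv``, ``report.json``, ``report.md``, ``regression.csv`` and
    ``run.log`` into the output directory.  On stage failure a ``FAILED``
    marker naming the stage is left next to any partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    stage = "setup"
    header = f"# bzra {__version__} | config {cfg_hash} | seed {config.seed}\n"
    log_lines = [header]
    try:
        registry, indications = load_registry(config.registry_path)

        stage = "simulate"
        if config.simulate is not None:
            sim = config.simulate.model_copy(update={"seed": config.seed})
            csv_path = out / "prescriptions.csv"
            n_rows = write_cohort(generate_cohort(sim, registry, indications), csv_path)
            log_lines.append(f"simulate: {n_rows} records -> {csv_path}\n")
        elif config.input_csv is not None:
            csv_path = Path(config.input_csv)
            if not csv_path.exists():
                raise FileNotFoundError(f"input CSV not found: {csv_path}")
        else:
            raise ValueError("RunConfig needs input_csv or simulate")

        stage = "ingest"
        cohort = read_prescriptions(csv_path, registry)
        log_lines.append(
            f"ingest: {len(cohort.records)} records retained, "
            f"{cohort.excluded_count} excluded {dict(cohort.exclusion_reasons)}, "
            f"year {cohort.study_year}\n"
        )

        stage = "exposure"
        metrics = compute_cohort_metrics(
            cohort.records, registry, cohort.study_year,
            window_days=config.window_days, max_gap=config.max_gap,
        )
        metrics.to_csv(out / "metrics.csv", index=False)

        stage = "classify"
        thresholds = Thresholds(
            dme_threshold=config.dme_threshold,
            day_threshold=config.day_threshold,
            max_gap=config.max_gap,
            window_days=config.window_days,
        )
        labels = label_cohort(metrics, cohort.records, indications, thresholds)
        labels.to_csv(out / "labels.csv", index=False)
        log_lines.append(
            f"classify: thresholds dme>{thresholds.dme_threshold}, "
            f"days>={thresholds.day_threshold}, max_gap={thresholds.max_gap}, "
            f"window={thresholds.window_days}\n"
        )

        stage = "report"
        report = summarize_cohort(
            metrics, labels, cohort.records, registry,
            n_total_outpatients=config.n_total_outpatients,
        )
        per_drug_rows = []
        for pid, group in cohort.records.groupby("patient_id"):
            for drug, flag in per_drug_over_indication(group, indications).items():
                per_drug_rows.append(
                    {"patient_id": pid, "drug_id": drug, "over_indication": flag}
                )
        oi_rank = over_indication_report(cohort.records, labels, pd.DataFrame(per_drug_rows))
        report["over_indication_ranking"] = oi_rank.to_dict(orient="records")
        report["run"] = {"config_hash": cfg_hash, "seed": config.seed}
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "report.md").write_text(render_report_markdown(report))

        stage = "regression"
        demo = cohort.records.groupby("patient_id").agg(
            gender=("gender", "first"), age_years=("age_years", "first")
        ).reset_index()
        cohort_table = metrics.merge(labels[["patient_id", "hazardous", "over_indication"]],
                                     on="patient_id").merge(demo, on="patient_id")
        cohort_table["age_group"] = [age_group(a) for a in cohort_table["age_years"]]
        region_map = config.region_map or hospital_regions(
            cohort.records["hospital_id"].nunique()
        )
        regression_table = None
        if cohort_table["hospital_id"].nunique() >= 2 and cohort_table["hazardous"].any():
            design, n_dropped = build_design(cohort_table, region_map=region_map)
            result = fit_multilevel(design, family=config.family, n_dropped_missing=n_dropped)
            regression_table = result.params.copy()
            regression_table.index.name = "covariate"
            regression_table.to_csv(out / "regression.csv")
            log_lines.append(
                f"regression: family={result.family}, n_used={result.n_used}, "
                f"n_dropped_missing={result.n_dropped_missing}, "
                f"re_var={result.random_intercept_var:.6g}\n"
            )
        else:
            result = None
            log_lines.append("regression: skipped (needs >=2 hospitals and >=1 hazardous patient)\n")

        (out / "run.log").write_text("".join(log_lines))
        return {
            "cohort": cohort,
            "metrics": metrics,
            "labels": labels,
            "report": report,
            "regression": result,
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        log_lines.append(f"FAILED at stage {stage}: {exc}\n")
        (out / "run.log").write_text("".join(log_lines))
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise
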