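"""Descriptive reporting and classical group comparisons."""

import json

import numpy as np
import pandas as pd
import pytest

from bzra.classification import label_cohort
from bzra.cohort_stats import (
    classify_drug_use,
    compare_groups,
    ddd_consumption,
    diagnosis_blocks_of,
    over_indication_report,
    render_report_markdown,
    summarize_cohort,
)
from bzra.exposure import compute_cohort_metrics
from bzra.ingest import truncate_frame
from bzra.records import records_to_frame
from bzra.registry import load_registry
from bzra.synthetic import CohortConfig, generate_cohort

from .conftest import make_record, records_frame


class TestDrugUseClass:
    @pytest.mark.parametrize(
        "drugs, expected",
        [
            ({"clonazepam"}, "BZD_only"),
            ({"zolpidem", "zopiclone"}, "Z_only"),
            ({"diazepam", "zolpidem"}, "both"),
        ],
    )
    def test_class_from_dispensed_set(self, registry, drugs, expected):
        assert classify_drug_use(drugs, registry) == expected


class TestDiagnosisBlocks:
    @pytest.mark.parametrize(
        "code, blocks",
        [
            ("F32.1", ["F30-F39"]),
            ("G47.0", ["G47"]),
            ("F99", ["F99"]),
            ("G40", ["G40-G41"]),
            ("I10", []),
        ],
    )
    def test_block_lookup(self, code, blocks):
        assert diagnosis_blocks_of(code) == blocks


class TestDddConsumption:
    def test_one_ddd_per_day_at_ddd_dose(self, registry):
        ddd = registry.spec("diazepam").ddd_mg
        frame = records_frame(make_record(daily_dose_mg=ddd, days_supplied=10))
        total = ddd_consumption(frame, registry, by=())
        assert total == pytest.approx(10.0)

    def test_doubling_doses_doubles_cells(self, registry):
        frame = records_frame(
            make_record(drug_id="zolpidem", daily_dose_mg=10, days_supplied=5),
            make_record(drug_id="diazepam", daily_dose_mg=5, days_supplied=7,
                        hospital_id="H02"),
        )
        doubled = frame.assign(daily_dose_mg=frame["daily_dose_mg"] * 2)
        a = ddd_consumption(frame, registry)
        b = ddd_consumption(doubled, registry)
        assert np.allclose(b.values, 2 * a.values)


class TestCompareGroups:
    def test_identical_groups_wilcoxon_null(self):
        x = pd.Series(list(range(30)) * 2, dtype=float)
        g = pd.Series(["a"] * 30 + ["b"] * 30)
        res = compare_groups(x, g)
        assert res.test_name == "wilcoxon_rank"
        assert res.p_value > 0.9
        assert res.statistic == pytest.approx(30 * 30 / 2)  # null centre of the U statistic

    def test_balanced_2x2_chi_square_zero(self):
        values = pd.Series(["y"] * 10 + ["n"] * 10 + ["y"] * 10 + ["n"] * 10)
        groups = pd.Series(["a"] * 20 + ["b"] * 20)
        res = compare_groups(values, groups)
        assert res.test_name == "chi_square"
        assert res.statistic == 0.0

    def test_three_groups_use_kruskal(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.normal(size=90))
        g = pd.Series(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        res = compare_groups(x, g)
        assert res.test_name == "kruskal_wallis"
        assert 0 <= res.p_value <= 1
        assert res.group_sizes == (30, 30, 30)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))


@pytest.fixture(scope="module")
def small_cohort():
    registry, indications = load_registry()
    records = truncate_frame(
        records_to_frame(
            list(generate_cohort(CohortConfig(n_patients=300, seed=8), registry, indications))
        ),
        2018,
    )
    metrics = compute_cohort_metrics(records, registry, 2018)
    labels = label_cohort(metrics, records, indications)
    return registry, records, metrics, labels


class TestSummarizeCohort:
    def test_single_patient_degenerate_iqr(self, registry, indications, single_course_frame):
        metrics = compute_cohort_metrics(single_course_frame, registry, 2018)
        labels = label_cohort(metrics, single_course_frame, indications)
        report = summarize_cohort(metrics, labels, single_course_frame, registry)
        stats = report["metrics_overall"]["total_dme"]
        assert stats["median"] == stats["q1"] == stats["q3"] == pytest.approx(100.0)

    def test_two_patient_class_split(self, registry, indications):
        frame = records_frame(
            make_record(patient_id="A", drug_id="clonazepam", daily_dose_mg=0.5),
            make_record(patient_id="B", drug_id="zolpidem", daily_dose_mg=10),
        )
        metrics = compute_cohort_metrics(frame, registry, 2018)
        labels = label_cohort(metrics, frame, indications)
        report = summarize_cohort(metrics, labels, frame, registry)
        assert report["drug_class_use_pct"] == {"BZD_only": 50.0, "Z_only": 50.0, "both": 0.0}

    def test_exhaustive_proportions_sum_to_100(self, small_cohort):
        registry, records, metrics, labels = small_cohort
        report = summarize_cohort(metrics, labels, records, registry)
        for key in ("gender_pct", "age_group_pct"):
            assert sum(report["demographics"][key].values()) == pytest.approx(100.0)
        assert sum(report["drug_class_use_pct"].values()) == pytest.approx(100.0)

    def test_prevalence_arithmetic_exact(self, small_cohort):
        registry, records, metrics, labels = small_cohort
        report = summarize_cohort(metrics, labels, records, registry)
        n, pct = report["n_bzra_patients"], report["hazardous"]["pct"]
        assert round(n * pct / 100.0) == report["hazardous"]["count"]

    def test_iqr_ordering(self, small_cohort):
        registry, records, metrics, labels = small_cohort
        report = summarize_cohort(metrics, labels, records, registry)
        for stats in report["metrics_overall"].values():
            assert stats["q1"] <= stats["median"] <= stats["q3"]

    def test_report_is_pure_function(self, small_cohort):
        registry, records, metrics, labels = small_cohort
        r1 = summarize_cohort(metrics, labels, records, registry)
        r2 = summarize_cohort(metrics, labels, records, registry)
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)

    def test_markdown_rendering_mentions_key_numbers(self, small_cohort):
        registry, records, metrics, labels = small_cohort
        report = summarize_cohort(metrics, labels, records, registry)
        text = render_report_markdown(report)
        assert f"Patients on BZRAs: {len(metrics)}" in text
        assert "## Hazardous use" in text


class TestOverIndicationReport:
    def test_no_over_indication_patients_empty_ranking(self):
        labels = pd.DataFrame({"patient_id": ["A"], "over_indication": [False]})
        flags = pd.DataFrame(columns=["patient_id", "drug_id", "over_indication"])
        records = records_frame(make_record(patient_id="A"))
        assert over_indication_report(records, labels, flags).empty

    def test_single_patient_single_drug_is_100pct(self):
        labels = pd.DataFrame({"patient_id": ["A"], "over_indication": [True]})
        flags = pd.DataFrame(
            {"patient_id": ["A"], "drug_id": ["clonazepam"], "over_indication": [True]}
        )
        records = records_frame(
            make_record(patient_id="A", drug_id="clonazepam", diagnoses=("F32.1",))
        )
        out = over_indication_report(records, labels, flags)
        assert len(out) == 1
        assert out.loc[0, "drug_id"] == "clonazepam"
        assert out.loc[0, "pct_of_over_indication_patients"] == 100.0
        assert out.loc[0, "top_blocks"][0]["block"] == "F30-F39"
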