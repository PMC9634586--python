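"""Daily dose arrays, windowed maxima and gap-bridged episode detection."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bzra.exposure import (
    build_daily_array,
    compute_metrics,
    detect_max_run,
    max_window_average,
)

from .conftest import make_record, records_frame
from .oracles import brute_max_run, brute_max_window_average


def day_array(use_days, value=10.0, n=365):
    arr = np.zeros(n)
    arr[list(use_days)] = value
    return arr


class TestDailyArray:
    def test_single_course_accumulates(self, registry, single_course_frame):
        """0.5 mg/day clonazepam for 10 days -> ten days at 10 DME, total 100."""
        arr = build_daily_array(single_course_frame, registry, 2018)
        assert len(arr.dme_by_day) == 365
        jan1 = dt.date(2018, 1, 1)
        start = (dt.date(2018, 3, 1) - jan1).days
        assert np.all(arr.dme_by_day[start : start + 10] == 10.0)
        assert arr.dme_by_day.sum() == pytest.approx(100.0)
        assert np.count_nonzero(arr.dme_by_day) == 10

    def test_no_records_gives_zero_array(self, registry):
        arr = build_daily_array(records_frame(), registry, 2018)
        assert arr.dme_by_day.sum() == 0.0

    def test_overlapping_records_stack(self, registry):
        """Two identical zolpidem 20 mg/day courses on the same 5 days sum to 20 DME."""
        rec = dict(drug_id="zolpidem", daily_dose_mg=20.0, days_supplied=5)
        frame = records_frame(make_record(**rec), make_record(doctor_id="D2", **rec))
        arr = build_daily_array(frame, registry, 2018)
        assert np.count_nonzero(arr.dme_by_day) == 5
        assert set(arr.dme_by_day[arr.dme_by_day > 0]) == {20.0}

    def test_mixed_patients_rejected(self, registry):
        frame = records_frame(make_record(patient_id="A"), make_record(patient_id="B"))
        with pytest.raises(ValueError, match="several patients"):
            build_daily_array(frame, registry, 2018)

    def test_untruncated_record_rejected(self, registry):
        frame = records_frame(
            make_record(visit_date=dt.date(2018, 12, 25), days_supplied=30)
        )
        with pytest.raises(ValueError, match="truncate"):
            build_daily_array(frame, registry, 2018)

    def test_leap_year_length(self, registry):
        frame = records_frame(make_record(visit_date=dt.date(2020, 2, 29)))
        arr = build_daily_array(frame, registry, 2020)
        assert len(arr.dme_by_day) == 366


class TestMaxWindowAverage:
    def test_all_zero(self):
        assert max_window_average(np.zeros(365), 90) == 0.0

    def test_constant_array(self):
        assert max_window_average(np.full(365, 10.0), 90) == pytest.approx(10.0)

    def test_short_burst_diluted_by_window(self):
        """30 days at 90 DME average to 30 over the best 90-day window."""
        arr = day_array(range(100, 130), value=90.0)
        assert max_window_average(arr, 90) == pytest.approx(30.0)

    def test_window_bounds_validated(self):
        with pytest.raises(ValueError):
            max_window_average(np.zeros(10), 0)
        with pytest.raises(ValueError):
            max_window_average(np.zeros(10), 11)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(data=st.data())
    def test_matches_exhaustive_window_scan(self, data):
        n = data.draw(st.integers(1, 366))
        window = data.draw(st.integers(1, n))
        arr = np.array(data.draw(
            st.lists(st.floats(0, 200, allow_nan=False), min_size=n, max_size=n)
        ))
        assert max_window_average(arr, window) == pytest.approx(
            brute_max_window_average(arr, window), rel=1e-9, abs=1e-9
        )


class TestDetectMaxRun:
    def test_gap_of_three_bridges(self):
        """Use on days 1-10 and 14-20 (3-day gap) merges into a 20-day span."""
        arr = day_array(list(range(0, 10)) + list(range(13, 20)))
        assert detect_max_run(arr, max_gap=3) == 20

    def test_gap_of_four_breaks(self):
        arr = day_array(list(range(0, 10)) + list(range(14, 20)))
        assert detect_max_run(arr, max_gap=3) == 10

    def test_no_use_days(self):
        assert detect_max_run(np.zeros(365), 3) == 0

    def test_zero_gap_is_plain_run_length(self):
        arr = day_array(list(range(5, 12)) + list(range(13, 16)))
        assert detect_max_run(arr, max_gap=0) == 7

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(data=st.data())
    def test_matches_pairwise_enumeration(self, data):
        n = data.draw(st.integers(1, 366))
        max_gap = data.draw(st.sampled_from([0, 1, 2, 3, 5]))
        arr = np.array(data.draw(
            st.lists(st.sampled_from([0.0, 1.0]), min_size=n, max_size=n)
        ))
        assert detect_max_run(arr, max_gap) == brute_max_run(arr, max_gap)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(data=st.data())
    def test_nondecreasing_in_max_gap(self, data):
        n = data.draw(st.integers(1, 200))
        arr = np.array(data.draw(
            st.lists(st.sampled_from([0.0, 1.0]), min_size=n, max_size=n)
        ))
        runs = [detect_max_run(arr, g) for g in range(6)]
        assert runs == sorted(runs)


class TestComputeMetrics:
    def test_single_course_metrics(self, registry, single_course_frame):
        m = compute_metrics(single_course_frame, registry, 2018)
        assert m.max_window_avg_dme == pytest.approx(100.0 / 90.0)
        assert m.total_dme == pytest.approx(100.0)
        assert m.max_continuous_days == 10
        assert m.total_days_of_use == 10
        assert m.n_visits == 1
        assert m.n_distinct_doctors == 1
        assert m.average_daily_dme == pytest.approx(10.0)

    def test_visit_and_doctor_counting(self, registry):
        frame = records_frame(
            make_record(doctor_id="D1", visit_date=dt.date(2018, 1, 5)),
            make_record(doctor_id="D2", visit_date=dt.date(2018, 2, 5)),
            make_record(doctor_id="D1", visit_date=dt.date(2018, 3, 5)),
        )
        m = compute_metrics(frame, registry, 2018)
        assert m.n_visits == 3
        assert m.n_distinct_doctors == 2

    def test_empty_record_set_rejected(self, registry):
        with pytest.raises(ValueError):
            compute_metrics(records_frame(), registry, 2018)

    def test_adding_a_prescription_never_decreases_metrics(self, registry):
        base = [
            make_record(visit_date=dt.date(2018, 2, 1), days_supplied=20),
            make_record(visit_date=dt.date(2018, 5, 1), days_supplied=10),
        ]
        extra = make_record(
            visit_date=dt.date(2018, 2, 25), days_supplied=15, doctor_id="D9"
        )
        m0 = compute_metrics(records_frame(*base), registry, 2018)
        m1 = compute_metrics(records_frame(*base, extra), registry, 2018)
        assert m1.total_dme >= m0.total_dme
        assert m1.max_window_avg_dme >= m0.max_window_avg_dme
        assert m1.total_days_of_use >= m0.total_days_of_use
        assert m1.max_continuous_days >= m0.max_continuous_days
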