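import datetime as dt

import pandas as pd
import pytest

from bzra.records import PrescriptionRecord
from bzra.registry import load_registry


@pytest.fixture(scope="session")
def registry():
    table, _ = load_registry()
    return table


@pytest.fixture(scope="session")
def indications():
    _, imap = load_registry()
    return imap


def make_record(
    patient_id="P1",
    hospital_id="H01",
    doctor_id="D1",
    visit_date=dt.date(2018, 3, 1),
    drug_id="diazepam",
    daily_dose_mg=10.0,
    days_supplied=10,
    diagnoses=("F41.1",),
    gender="female",
    age_years=40,
):
    return PrescriptionRecord(
        patient_id=patient_id,
        hospital_id=hospital_id,
        doctor_id=doctor_id,
        visit_date=visit_date,
        drug_id=drug_id,
        daily_dose_mg=daily_dose_mg,
        days_supplied=days_supplied,
        diagnoses=list(diagnoses),
        gender=gender,
        age_years=age_years,
    )


def records_frame(*records):
    from bzra.records import records_to_frame

    return records_to_frame(list(records))


@pytest.fixture
def single_course_frame():
    """One patient, one 10-day course of clonazepam 0.5 mg/day (10 DME/day)."""
    return records_frame(
        make_record(drug_id="clonazepam", daily_dose_mg=0.5, days_supplied=10)
    )
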