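"""Seeded synthetic prescription databases with planted usage phenotypes.

Real hospital dispensing databases of this kind cannot be shared, so the
pipeline is exercised on synthetic cohorts that reproduce the *structure* the
analysis assumes: a one-year observation window, a majority of short-term
low-dose users, and minorities of long-term, high-dose, doctor-shopping and
jointly hazardous users, nested in a small number of hospitals.

Patients are drawn from one of five archetypes:

``casual``
    1-3 dispensings of a low daily dose (well under the 40 DME/day overdose
    line even if dispensings overlap) over short spans.
``long_term_stable``
    back-to-back refills (gaps of at most 3 days) spanning at least 100 days
    at a sub-threshold dose — long-term but never overdose.
``short_overdose``
    a supra-threshold dose over a span of at most 60 days — overdose but
    never long-term.
``hazardous``
    refills constructed to exceed BOTH rules: a gap-bridged run of at least
    95 days and a 90-day window average above 40 DME/day.
``doctor_shopper``
    many low-dose dispensings from many distinct doctors.

Planting is constructive — refill dates and doses are computed to clear (or
stay clear of) the classification thresholds with margin — so the archetype
determines the downstream label and recovery tests are sharp.

Over-indication status is likewise planted per patient: with probability
``over_indication_prob`` all of the patient's year diagnoses are drawn from
ICD-10 blocks disjoint from every dispensed drug's approved indications.
"""

from __future__ import annotations

import datetime as dt
import calendar
from typing import Iterator

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .records import PrescriptionRecord
from .registry import DMETable, IndicationMap, load_registry

__all__ = [
    "ARCHETYPES",
    "CohortConfig",
    "EffectConfig",
    "generate_cohort",
    "write_cohort",
    "hospital_regions",
    "simulate_regression_cohort",
]

ARCHETYPES = ("casual", "long_term_stable", "short_overdose", "hazardous", "doctor_shopper")

#: classification thresholds the planting is constructed around
_DME_THRESHOLD = 40.0
_DAY_THRESHOLD = 90

#: diagnosis codes that match no drug's approved indications in the default
#: registry (mood disorders, schizophrenia, unspecified) — the off-label pool
_NON_INDICATION_CODES = [
    "F20.0", "F20.9", "F25.1", "F31.1", "F32.0", "F32.1", "F32.9",
    "F33.1", "F33.2", "F39", "F99",
]

#: marginal drug popularity, loosely matching observed prescribing frequency
_DRUG_WEIGHTS = {
    "clonazepam": 0.25, "alprazolam": 0.18, "eszopiclone": 0.13,
    "zolpidem": 0.12, "estazolam": 0.08, "lorazepam": 0.07,
    "zopiclone": 0.06, "oxazepam": 0.05, "diazepam": 0.035,
    "zaleplon": 0.015, "nitrazepam": 0.01, "midazolam": 0.01,
}


class EffectConfig(BaseModel):
    """Planted linear-probability coefficients for the regression-recovery design.

    Coefficients are risk differences for a binary hazardous-use outcome;
    counts (visits, doctors) enter per unit.  ``hospital_sd`` is the standard
    deviation of the Gaussian hospital random intercept.
    """

    # baseline keeps the linear predictor positive for every covariate
    # pattern, so clipping to [0, 1] is a guard, not a source of bias
    intercept: float = 0.01
    age_18_64: float = 0.018
    age_65_plus: float = 0.015
    male: float = 0.005
    region_central: float = 0.0
    region_west: float = 0.0
    over_indication: float = 0.013
    n_visits: float = 0.006
    n_distinct_doctors: float = 0.007
    hospital_sd: float = Field(default=0.01, ge=0.0)


class CohortConfig(BaseModel):
    """Configuration of one synthetic cohort."""

    n_patients: int = Field(gt=0)
    n_hospitals: int = Field(default=5, ge=1)
    year: int = 2018
    seed: int = 0
    archetype_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "casual": 0.80,
            "long_term_stable": 0.09,
            "short_overdose": 0.04,
            "hazardous": 0.03,
            "doctor_shopper": 0.04,
        }
    )
    over_indication_prob: float = Field(default=0.559, ge=0.0, le=1.0)
    gender_probs: dict[str, float] = Field(
        default_factory=lambda: {"female": 0.636, "male": 0.364}
    )
    age_group_probs: dict[str, float] = Field(
        default_factory=lambda: {"<18": 0.03, "18-64": 0.762, ">=65": 0.208}
    )
    missing_prob: float = Field(default=0.02, ge=0.0, le=1.0)
    effects: EffectConfig = Field(default_factory=EffectConfig)

    @field_validator("archetype_mix")
    @classmethod
    def _check_mix(cls, mix: dict[str, float]) -> dict[str, float]:
        unknown = set(mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype(s) {sorted(unknown)}")
        if any(p < 0 or p > 1 for p in mix.values()):
            raise ValueError("archetype proportions must lie in [0, 1]")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"archetype_mix must sum to 1, got {sum(mix.values())}")
        return mix

    @model_validator(mode="after")
    def _check_sizes(self) -> "CohortConfig":
        if self.n_patients < self.n_hospitals:
            raise ValueError("n_patients must be at least n_hospitals")
        for name in ("gender_probs", "age_group_probs"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        return self


def hospital_regions(n_hospitals: int) -> dict[str, str]:
    """Deterministic hospital → region map (east/central/west China analogue).

    For the default five hospitals the layout mirrors the study design: two
    eastern, one western, two central sites.
    """
    if n_hospitals == 5:
        layout = ["east", "east", "west", "central", "central"]
    else:
        layout = [["east", "central", "west"][i % 3] for i in range(n_hospitals)]
    return {f"H{i + 1:02d}": layout[i] for i in range(n_hospitals)}


def _year_days(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def _pick_drugs(rng: np.random.Generator, n: int = 1) -> list[str]:
    drugs = list(_DRUG_WEIGHTS)
    probs = np.array(list(_DRUG_WEIGHTS.values()))
    probs = probs / probs.sum()
    return [str(d) for d in rng.choice(drugs, size=n, replace=False, p=probs)]


def _dose_mg(registry: DMETable, drug: str, dme: float) -> float:
    return round(dme / registry.spec(drug).dme_per_mg, 3)


def _sample_demographics(rng: np.random.Generator, config: CohortConfig) -> tuple[str, int]:
    gender = str(rng.choice(list(config.gender_probs), p=list(config.gender_probs.values())))
    group = str(rng.choice(list(config.age_group_probs), p=list(config.age_group_probs.values())))
    if group == "<18":
        age = int(rng.integers(10, 18))
    elif group == "18-64":
        age = int(rng.integers(18, 65))
    else:
        age = int(rng.integers(65, 91))
    return gender, age


def _sample_diagnoses(
    rng: np.random.Generator,
    drugs: list[str],
    indications: IndicationMap,
    over_indication: bool,
) -> list[str]:
    n_extra = int(rng.integers(0, 3))
    extra = [str(c) for c in rng.choice(_NON_INDICATION_CODES, size=n_extra, replace=False)]
    if over_indication:
        base = str(rng.choice(_NON_INDICATION_CODES))
        codes = {base, *extra}
    else:
        drug = str(rng.choice(drugs))
        stem = str(rng.choice(sorted(indications.stems(drug))))
        codes = {stem + "." + str(rng.integers(0, 10)), *extra}
    return sorted(codes)


def _refill_chain(
    rng: np.random.Generator,
    year: int,
    min_span: int,
    max_start_slack: bool = True,
) -> list[tuple[int, int]]:
    """Back-to-back refills (day-offset, days_supplied) with gaps <= 3 days,
    chained until the calendar span reaches ``min_span``, placed so the whole
    episode fits inside the year."""
    segments: list[tuple[int, int]] = []
    day = 0
    while True:
        supply = int(rng.integers(28, 31))
        segments.append((day, supply))
        span = segments[-1][0] + segments[-1][1]
        if span >= min_span:
            break
        day = span + int(rng.integers(0, 4))  # gap of 0-3 non-use days
    span = segments[-1][0] + segments[-1][1]
    start = int(rng.integers(0, _year_days(year) - span + 1)) if max_start_slack else 0
    return [(start + off, supply) for off, supply in segments]


def _patient_dispensings(
    rng: np.random.Generator,
    archetype: str,
    year: int,
    registry: DMETable,
) -> list[tuple[int, str, float, int]]:
    """Return (day_offset, drug_id, daily_dose_mg, days_supplied) tuples."""
    ydays = _year_days(year)
    out: list[tuple[int, str, float, int]] = []

    if archetype == "casual":
        drugs = _pick_drugs(rng, 2 if rng.random() < 0.15 else 1)
        for _ in range(int(rng.integers(1, 4))):
            drug = str(rng.choice(drugs))
            dme = min(float(rng.lognormal(np.log(8.0), 0.6)), 30.0)
            out.append((int(rng.integers(0, ydays)), drug,
                        _dose_mg(registry, drug, dme), int(rng.integers(3, 15))))

    elif archetype == "long_term_stable":
        drug = _pick_drugs(rng)[0]
        dme = float(rng.uniform(5.0, 35.0))  # sub-threshold: never overdose
        for day, supply in _refill_chain(rng, year, min_span=int(rng.integers(100, 180))):
            out.append((day, drug, _dose_mg(registry, drug, dme), supply))

    elif archetype == "short_overdose":
        drug = _pick_drugs(rng)[0]
        dme = float(rng.uniform(90.0, 160.0))  # 45+ DME/day averaged over 90 days
        total = int(rng.integers(45, 61))  # two refills of <= 30 days each
        start = int(rng.integers(0, ydays - total - 1))
        day = start
        for i in range(2):
            supply = total // 2 + (1 if i < total % 2 else 0)
            out.append((day, drug, _dose_mg(registry, drug, dme), supply))
            day += supply + int(rng.integers(0, 2))
        # episode span <= 61 days: at most one 1-day gap between the refills

    elif archetype == "hazardous":
        drug = _pick_drugs(rng)[0]
        dme = float(rng.uniform(50.0, 120.0))  # supra-threshold with margin
        for day, supply in _refill_chain(rng, year, min_span=int(rng.integers(95, 150))):
            out.append((day, drug, _dose_mg(registry, drug, dme), supply))

    elif archetype == "doctor_shopper":
        drugs = _pick_drugs(rng, 2 if rng.random() < 0.4 else 1)
        for _ in range(int(rng.integers(8, 16))):
            drug = str(rng.choice(drugs))
            dme = float(rng.uniform(2.0, 20.0))
            out.append((int(rng.integers(0, ydays)), drug,
                        _dose_mg(registry, drug, dme), int(rng.integers(3, 11))))
    else:  # pragma: no cover
        raise ValueError(f"unknown archetype {archetype!r}")
    return out


def generate_cohort(
    config: CohortConfig,
    registry: DMETable | None = None,
    indications: IndicationMap | None = None,
) -> Iterator[PrescriptionRecord]:
    """Yield one synthetic cohort of prescription records, deterministic in the seed."""
    if registry is None or indications is None:
        registry, indications = load_registry()
    rng = np.random.default_rng(config.seed)
    jan1 = dt.date(config.year, 1, 1)
    regions = hospital_regions(config.n_hospitals)
    hospitals = sorted(regions)
    # one doctor pool per hospital
    doctor_pools = {h: [f"{h}-D{i:03d}" for i in range(40)] for h in hospitals}

    mix_names = [a for a in ARCHETYPES if config.archetype_mix.get(a, 0.0) > 0]
    mix_probs = np.array([config.archetype_mix[a] for a in mix_names])
    mix_probs = mix_probs / mix_probs.sum()

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        hospital = hospitals[i % config.n_hospitals] if i < config.n_hospitals else str(rng.choice(hospitals))
        archetype = str(rng.choice(mix_names, p=mix_probs))
        gender, age = _sample_demographics(rng, config)
        dispensings = _patient_dispensings(rng, archetype, config.year, registry)
        drugs = sorted({d for _, d, _, _ in dispensings})
        over_ind = bool(rng.random() < config.over_indication_prob)
        diagnoses = _sample_diagnoses(rng, drugs, indications, over_ind)

        pool = doctor_pools[hospital]
        if archetype == "doctor_shopper":
            doctors = [str(rng.choice(pool)) for _ in dispensings]
        else:
            primary = str(rng.choice(pool))
            doctors = [primary if rng.random() < 0.8 else str(rng.choice(pool)) for _ in dispensings]

        # exercise the missing-demographics exclusion path
        missing_gender = rng.random() < config.missing_prob
        missing_age = rng.random() < config.missing_prob
        missing_dx = rng.random() < config.missing_prob

        for (day, drug, dose, supply), doctor in zip(dispensings, doctors):
            yield PrescriptionRecord(
                patient_id=pid,
                hospital_id=hospital,
                doctor_id=doctor,
                visit_date=jan1 + dt.timedelta(days=day),
                drug_id=drug,
                daily_dose_mg=dose,
                days_supplied=supply,
                diagnoses=[] if missing_dx else diagnoses,
                gender="unknown" if missing_gender else gender,
                age_years=None if missing_age else age,
            )


def write_cohort(records, path) -> int:
    """Write a record stream as CSV (see :mod:`bzra.records` for the dialect)."""
    from .records import write_records_csv

    return write_records_csv(records, path)


def simulate_regression_cohort(
    effects: EffectConfig,
    n: int = 20_000,
    n_hospitals: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a model-ready design for the parameter-recovery experiment.

    Covariates are drawn from cohort-realistic marginals, a Gaussian hospital
    intercept is added, and the binary hazardous outcome is Bernoulli with a
    linear-probability mean (clipped to [0, 1]).  Returns the design table
    accepted by :func:`bzra.regression.fit_multilevel`, plus the ``hazardous``
    outcome column.
    """
    rng = np.random.default_rng(seed)
    regions = hospital_regions(n_hospitals)
    hospitals = sorted(regions)
    hosp_effect = dict(zip(hospitals, rng.normal(0.0, effects.hospital_sd, n_hospitals)))

    hospital = rng.choice(hospitals, size=n)
    age_group = rng.choice(["<18", "18-64", ">=65"], size=n, p=[0.03, 0.762, 0.208])
    male = rng.random(n) < 0.364
    over_ind = rng.random(n) < 0.559
    n_visits = 1 + rng.poisson(2.5, n)
    extra = rng.binomial(n_visits - 1, 0.5)
    n_doctors = 1 + extra

    region = np.array([regions[h] for h in hospital])
    lin = (
        effects.intercept
        + effects.age_18_64 * (age_group == "18-64")
        + effects.age_65_plus * (age_group == ">=65")
        + effects.male * male
        + effects.region_central * (region == "central")
        + effects.region_west * (region == "west")
        + effects.over_indication * over_ind
        + effects.n_visits * n_visits
        + effects.n_distinct_doctors * n_doctors
        + np.array([hosp_effect[h] for h in hospital])
    )
    p = np.clip(lin, 0.0, 1.0)
    hazardous = rng.random(n) < p
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "hospital_id": hospital,
            "region": region,
            "age_group": age_group,
            "gender": np.where(male, "male", "female"),
            "over_indication": over_ind.astype(int),
            "n_visits": n_visits.astype(int),
            "n_distinct_doctors": n_doctors.astype(int),
            "hazardous": hazardous.astype(int),
        }
    )
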