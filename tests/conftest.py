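"""Shared fixtures: record builders and simulated populations."""

from __future__ import annotations

import datetime as dt

import pytest

from t2d_cvd.claims_model import (
    ClaimsBundle,
    DiagnosisRecord,
    LabServiceRecord,
    PersonClaims,
    PersonRecord,
    PrescriptionRecord,
    ProcedureRecord,
    Qualifier,
    Setting,
    Sex,
)
from t2d_cvd.cohort import build_cohort
from t2d_cvd.synthetic_claims import SimulationConfig, generate

FULL_SPAN = (dt.date(2010, 1, 1), dt.date(2015, 12, 31))


def make_person(
    pid: str = "P1",
    sex: Sex = Sex.female,
    birth_year: int = 1950,
    start: dt.date = FULL_SPAN[0],
    end: dt.date = FULL_SPAN[1],
    death: dt.date | None = None,
) -> PersonRecord:
    return PersonRecord(pid, sex, birth_year, start, end, death)


def dx(
    code: str,
    date: dt.date,
    setting: Setting = Setting.ambulatory,
    qualifier: Qualifier | None = Qualifier.G,
    pid: str = "P1",
) -> DiagnosisRecord:
    if setting is not Setting.ambulatory:
        qualifier = None
    return DiagnosisRecord(pid, code, setting, qualifier, date)


def rx(code: str, date: dt.date, prescriber: str = "DOC1", pid: str = "P1") -> PrescriptionRecord:
    return PrescriptionRecord(pid, code, date, prescriber)


def proc(code: str, date: dt.date, pid: str = "P1") -> ProcedureRecord:
    return ProcedureRecord(pid, code, date)


def lab(code: str, date: dt.date, physician: str = "DOC1", pid: str = "P1") -> LabServiceRecord:
    return LabServiceRecord(pid, code, date, physician)


def person_claims(person=None, diagnoses=(), prescriptions=(), procedures=(), labs=()) -> PersonClaims:
    return PersonClaims(
        person=person or make_person(),
        diagnoses=list(diagnoses),
        prescriptions=list(prescriptions),
        procedures=list(procedures),
        lab_services=list(labs),
    )


@pytest.fixture(scope="session")
def sim_small():
    """2,000-person simulation with churn and deaths, default parameters."""
    bundle, truth = generate(SimulationConfig(n_persons=2000, seed=11))
    return bundle, truth


@pytest.fixture(scope="session")
def cohort_small(sim_small):
    bundle, truth = sim_small
    return build_cohort(bundle), truth


@pytest.fixture(scope="session")
def sim_20k():
    """The mechanism-recovery population: 20,000 persons, doc_prob 0.5."""
    bundle, truth = generate(SimulationConfig(n_persons=20_000, seed=1, doc_prob=0.5))
    return bundle, truth


@pytest.fixture(scope="session")
def cohort_20k(sim_20k):
    bundle, truth = sim_20k
    return build_cohort(bundle), truth
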