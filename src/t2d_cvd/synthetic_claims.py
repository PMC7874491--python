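"""Synthetic SHI claims generator with known ground truth.

Emulates the structure of a German statutory-health-insurance research
extract: an age/sex-stratified insured population observed 2010-2015 with a
small enrollment churn, deaths truncating enrollment, latent chronic disease
states (type 2 diabetes, cardiovascular disease, hypertension, lipid
disorder), quarter-stamped ICD-10-GM diagnoses with ambulatory certainty
qualifiers, ATC-coded drug dispensations, OPS-coded hospital procedures and
EBM-coded lab billing tied to the prescribing physician.

The central behavioral assumption is a *per-year documentation probability*:
a prevalent chronic condition is coded at least once in a given year with
probability ``doc_prob``, independently across years.  Under that model the
fraction of truly ill persons visible in a window of ``y`` years is
``1 - (1 - doc_prob)**y`` — the mechanism by which observed prevalence of a
chronic condition grows with the observation period.

Ground truth (latent states, onset year, therapy class) is emitted alongside
the claims and is never consumed by the analysis modules.
"""

from __future__ import annotations

import datetime as dt
import random
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .claims_model import (
    ClaimsBundle,
    DiagnosisRecord,
    LabServiceRecord,
    PersonRecord,
    PrescriptionRecord,
    ProcedureRecord,
    Qualifier,
    Quarter,
    Setting,
    Sex,
)

__all__ = ["SimulationConfig", "generate", "expected_observed_fraction"]

STUDY_START = dt.date(2010, 1, 1)
STUDY_END = dt.date(2015, 12, 31)
INDEX_YEAR = 2015

#: Specific CVD component codes documented for a true-CVD person, spanning
#: all three definition tiers so that narrow < narrow+CHF < wide.
CVD_COMPONENT_ICD = (
    # narrow tier
    "I639", "I64", "I200", "I219", "I229", "I249", "I251", "I2512",
    "I739", "I7020",
    # CHF tier
    "I500", "I501", "I509",
    # wide-only tier
    "I609", "I619", "I629", "I208", "I209", "I2510", "I253",
)

CVD_COMPONENT_OPS = ("5-361", "5-362", "5-363", "8-836", "8-837", "8-840")

#: Irrelevant background codes; must never trigger any rule.
NOISE_ICD = ("J069", "M545", "K219", "E669", "F329", "I839", "H521")

EBM_GLUCOSE_CODES = ("32025", "32057", "32881", "32094")

#: Dispensed ATC codes per therapy class.
THERAPY_ATC: dict[str, tuple[tuple[str, ...], bool]] = {
    # label -> (non-insulin codes, insulin?)
    "none": ((), False),
    "metformin_mono": (("A10BA02",), False),
    "sulfonylurea_mono": (("A10BB01",), False),
    "dpp4_mono": (("A10BH01",), False),
    "glp1_mono": (("A10BJ02",), False),
    "sglt2_mono": (("A10BK01",), False),
    "glinide_mono": (("A10BX02",), False),
    "glucosidase_mono": (("A10BF01",), False),
    "dual_met_su": (("A10BA02", "A10BB01"), False),
    "dual_met_dpp4": (("A10BA02", "A10BH01"), False),
    "dual_other": (("A10BA02", "A10BK01"), False),
    "triple_plus": (("A10BA02", "A10BB01", "A10BH01"), False),
    "insulin_only": ((), True),
    "insulin_plus": (("A10BA02",), True),
}

_BANDS = ("under18", "18-39", "40-59", "60-79", "80plus")
_BAND_AGES = {
    "under18": (1, 17),
    "18-39": (18, 39),
    "40-59": (40, 59),
    "60-79": (60, 79),
    "80plus": (80, 94),
}


class SimulationConfig(BaseModel):
    """Parameters of the synthetic population and its documentation behavior.

    Defaults sketch the magnitudes of the German SHI population and of a
    T2D cohort drawn from it (adult T2D prevalence around 10%, CVD in about
    half the diabetic cohort over six years, hypertension in most of it);
    they are configuration, not estimates of German coding practice.
    """

    n_persons: int = Field(ge=0, default=10_000)
    seed: int = 1
    #: population shares per age band (must sum to 1, under-18 included)
    age_band_weights: dict[str, float] = {
        "under18": 0.16,
        "18-39": 0.26,
        "40-59": 0.29,
        "60-79": 0.22,
        "80plus": 0.07,
    }
    sex_ratio_female: float = Field(ge=0, le=1, default=0.51)
    t2d_prevalence_by_band: dict[str, float] = {
        "under18": 0.0,
        "18-39": 0.01,
        "40-59": 0.07,
        "60-79": 0.20,
        "80plus": 0.24,
    }
    cvd_given_t2d: float = Field(ge=0, le=1, default=0.5)
    cvd_given_no_t2d: float = Field(ge=0, le=1, default=0.08)
    #: per-year probability that a prevalent chronic condition is coded at all
    doc_prob: float = Field(ge=0, le=1, default=0.5)
    #: probability of an enrollment span not covering the full study period
    churn_prob: float = Field(ge=0, le=1, default=0.02)
    #: probability of dying during 2010-2015
    death_rate_by_band: dict[str, float] = {
        "under18": 0.0005,
        "18-39": 0.002,
        "40-59": 0.01,
        "60-79": 0.06,
        "80plus": 0.25,
    }
    #: therapy-class mix among true T2D persons
    therapy_mix: dict[str, float] = {
        "none": 0.302,
        "metformin_mono": 0.230,
        "sulfonylurea_mono": 0.022,
        "dpp4_mono": 0.021,
        "glp1_mono": 0.001,
        "sglt2_mono": 0.001,
        "glinide_mono": 0.004,
        "glucosidase_mono": 0.001,
        "dual_met_su": 0.033,
        "dual_met_dpp4": 0.066,
        "dual_other": 0.018,
        "triple_plus": 0.035,
        "insulin_only": 0.123,
        "insulin_plus": 0.143,
    }
    #: onset-year mix for prevalent T2D (2010 bucket = onset 2010 or earlier)
    t2d_onset_year_weights: dict[int, float] = {
        2010: 0.723,
        2011: 0.075,
        2012: 0.059,
        2013: 0.057,
        2014: 0.051,
        2015: 0.035,
    }
    #: probability a treated diabetic carries only unspecific E14 codes, never E11
    e14_miscoding_prob: float = Field(ge=0, le=1, default=0.025)
    #: probability a treated person's glucose labs are billed by the prescriber
    lab_pathway_prob: float = Field(ge=0, le=1, default=0.5)
    #: probability a treated year has dispensations in only one quarter
    low_adherence_prob: float = Field(ge=0, le=1, default=0.15)
    hypertension_given_t2d: float = Field(ge=0, le=1, default=0.85)
    hypertension_base: float = Field(ge=0, le=1, default=0.30)
    lipid_given_t2d: float = Field(ge=0, le=1, default=0.60)
    lipid_base: float = Field(ge=0, le=1, default=0.20)
    #: probability of one suspected (qualifier V) E11 row per person-year
    suspected_e11_noise_prob: float = Field(ge=0, le=1, default=0.01)
    noise_prob: float = Field(ge=0, le=1, default=0.3)

    @field_validator("age_band_weights", "t2d_prevalence_by_band", "death_rate_by_band")
    @classmethod
    def _bands_complete(cls, v: dict[str, float]) -> dict[str, float]:
        missing = set(_BANDS) - set(v)
        if missing:
            raise ValueError(f"missing age band(s) {sorted(missing)}")
        if any(not 0 <= p <= 1 for p in v.values()):
            raise ValueError("band probabilities must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _weights_sum(self) -> "SimulationConfig":
        for name in ("age_band_weights", "therapy_mix", "t2d_onset_year_weights"):
            total = sum(getattr(self, name).values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
        unknown = set(self.therapy_mix) - set(THERAPY_ATC)
        if unknown:
            raise ValueError(f"unknown therapy class(es) {sorted(unknown)}")
        return self


def expected_observed_fraction(doc_prob: float, window_years: int) -> float:
    """Fraction of truly ill persons with at least one code in a y-year window.

    Under independent per-year documentation this is ``1 - (1-p)**y``; it is
    strictly increasing in the window length for 0 < p < 1, which is why a
    single claims year understates the prevalence of chronic conditions.
    """
    if not 0 <= doc_prob <= 1:
        raise ValueError("doc_prob must lie in [0, 1]")
    if window_years < 1:
        raise ValueError("window must span at least one year")
    return 1.0 - (1.0 - doc_prob) ** window_years


def _weighted_choice(rng: random.Random, weights: dict) -> object:
    keys = list(weights)
    return rng.choices(keys, weights=[weights[k] for k in keys], k=1)[0]


def _date_in_quarter(rng: random.Random, q: Quarter, lo: dt.date, hi: dt.date) -> Optional[dt.date]:
    """Uniform date inside a quarter clipped to [lo, hi]; None if empty."""
    start = max(q.start, lo)
    end = min(q.end, hi)
    if start > end:
        return None
    return start + dt.timedelta(days=rng.randrange((end - start).days + 1))


def generate(config: SimulationConfig) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Generate a claims bundle and its ground-truth table.

    Deterministic: the same config (seed included) yields an identical
    bundle.  No claim row falls outside a person's enrollment span or after
    death.
    """
    rng = random.Random(config.seed)
    bundle = ClaimsBundle()
    truth_rows = []

    for i in range(config.n_persons):
        pid = f"P{i:07d}"
        band = _weighted_choice(rng, config.age_band_weights)
        lo_age, hi_age = _BAND_AGES[band]
        age = rng.randint(lo_age, hi_age)  # age at 1 Jan of the index year
        birth_year = INDEX_YEAR - age
        sex = Sex.female if rng.random() < config.sex_ratio_female else Sex.male

        # enrollment span; children born mid-study join at birth
        start = STUDY_START
        end = STUDY_END
        if birth_year >= STUDY_START.year:
            start = dt.date(birth_year + 1, 1, 1)
        if rng.random() < config.churn_prob:
            # a join or leave strictly inside the study period
            gap_day = STUDY_START + dt.timedelta(
                days=rng.randrange(180, (STUDY_END - STUDY_START).days - 180)
            )
            if gap_day > start:
                if rng.random() < 0.5:
                    start = gap_day
                else:
                    end = gap_day
        death_date: Optional[dt.date] = None
        if rng.random() < config.death_rate_by_band[band]:
            span = (end - start).days
            if span > 0:
                death_date = start + dt.timedelta(days=rng.randrange(span + 1))
                end = death_date
        person = PersonRecord(pid, sex, birth_year, start, end, death_date)
        bundle.persons.append(person)

        true_t2d = rng.random() < config.t2d_prevalence_by_band[band]
        true_cvd = rng.random() < (
            config.cvd_given_t2d if true_t2d else config.cvd_given_no_t2d
        )
        onset_year = (
            int(_weighted_choice(rng, config.t2d_onset_year_weights)) if true_t2d else 0
        )
        therapy = _weighted_choice(rng, config.therapy_mix) if true_t2d else "none"
        truth_rows.append(
            {
                "person_id": pid,
                "true_t2d": true_t2d,
                "true_cvd": true_cvd,
                "true_onset_year": onset_year,
                "therapy_class": therapy,
            }
        )

        _emit_person_claims(
            rng, config, bundle, person, true_t2d, true_cvd, onset_year, therapy
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["person_id", "true_t2d", "true_cvd", "true_onset_year", "therapy_class"],
    )
    return bundle, truth


def _emit_person_claims(
    rng: random.Random,
    config: SimulationConfig,
    bundle: ClaimsBundle,
    person: PersonRecord,
    true_t2d: bool,
    true_cvd: bool,
    onset_year: int,
    therapy: str,
) -> None:
    pid = person.person_id
    lo, hi = person.enrollment_start, person.enrollment_end
    years = range(max(STUDY_START.year, lo.year), min(INDEX_YEAR, hi.year) + 1)
    gp_id = f"D{rng.randrange(2000):05d}"  # stable prescribing physician
    lab_pathway = rng.random() < config.lab_pathway_prob
    miscoded_e14 = true_t2d and rng.random() < config.e14_miscoding_prob
    hypertensive = rng.random() < (
        config.hypertension_given_t2d if true_t2d else config.hypertension_base
    )
    dyslipidemic = rng.random() < (
        config.lipid_given_t2d if true_t2d else config.lipid_base
    )
    noninsulin_codes, insulin = THERAPY_ATC[therapy]

    def add_dx(code: str, day: dt.date, setting: Setting, qual: Optional[Qualifier]) -> None:
        bundle.diagnoses.append(DiagnosisRecord(pid, code, setting, qual, day))

    def dx_setting() -> tuple[Setting, Optional[Qualifier]]:
        u = rng.random()
        if u < 0.80:
            return Setting.ambulatory, Qualifier.G
        if u < 0.92:
            return Setting.hospital_secondary, None
        return Setting.hospital_main, None

    for year in years:
        quarters = [Quarter(year, q) for q in (1, 2, 3, 4)]

        # ---- glucose-lowering therapy --------------------------------
        if true_t2d and year >= onset_year and (noninsulin_codes or insulin):
            n_q = 1 if rng.random() < config.low_adherence_prob else rng.randint(2, 4)
            rx_quarters = rng.sample(quarters, n_q)
            first_lab_done = False
            for q in rx_quarters:
                day = _date_in_quarter(rng, q, lo, hi)
                if day is None:
                    continue
                for atc in noninsulin_codes:
                    bundle.prescriptions.append(PrescriptionRecord(pid, atc, day, gp_id))
                if insulin:
                    bundle.prescriptions.append(
                        PrescriptionRecord(pid, "A10AB01", day, gp_id)
                    )
                if lab_pathway and noninsulin_codes and not first_lab_done:
                    lab_day = _date_in_quarter(rng, q, lo, hi)
                    if lab_day is not None:
                        bundle.lab_services.append(
                            LabServiceRecord(
                                pid, rng.choice(EBM_GLUCOSE_CODES), lab_day, gp_id
                            )
                        )
                        first_lab_done = True

        # ---- diabetes diagnosis documentation ------------------------
        if true_t2d and year >= onset_year and rng.random() < config.doc_prob:
            # a documented year usually means several quarterly contacts
            n_q = 1 + sum(rng.random() < 0.75 for _ in range(3))
            for q in rng.sample(quarters, n_q):
                day = _date_in_quarter(rng, q, lo, hi)
                if day is None:
                    continue
                setting, qual = dx_setting()
                add_dx("E149" if miscoded_e14 else "E119", day, setting, qual)

        # ---- cardiovascular disease documentation --------------------
        if true_cvd and rng.random() < config.doc_prob:
            day = _date_in_quarter(rng, rng.choice(quarters), lo, hi)
            if day is not None:
                if rng.random() < 0.12:
                    # procedure-only year (revascularization admission)
                    bundle.procedures.append(
                        ProcedureRecord(pid, rng.choice(CVD_COMPONENT_OPS), day)
                    )
                else:
                    setting, qual = dx_setting()
                    add_dx(rng.choice(CVD_COMPONENT_ICD), day, setting, qual)
                    if rng.random() < 0.10:
                        bundle.procedures.append(
                            ProcedureRecord(pid, rng.choice(CVD_COMPONENT_OPS), day)
                        )

        # ---- comorbidities and background noise ----------------------
        if hypertensive and rng.random() < config.doc_prob:
            day = _date_in_quarter(rng, rng.choice(quarters), lo, hi)
            if day is not None:
                setting, qual = dx_setting()
                add_dx("I10", day, setting, qual)
        if dyslipidemic and rng.random() < config.doc_prob:
            day = _date_in_quarter(rng, rng.choice(quarters), lo, hi)
            if day is not None:
                setting, qual = dx_setting()
                add_dx("E780", day, setting, qual)
        if rng.random() < config.noise_prob:
            day = _date_in_quarter(rng, rng.choice(quarters), lo, hi)
            if day is not None:
                setting, qual = dx_setting()
                add_dx(rng.choice(NOISE_ICD), day, setting, qual)
        if not true_t2d and rng.random() < config.suspected_e11_noise_prob:
            day = _date_in_quarter(rng, rng.choice(quarters), lo, hi)
            if day is not None:
                add_dx("E119", day, Setting.ambulatory, Qualifier.V)
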