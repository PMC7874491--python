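"""Study-population selection and the four-criterion T2D case algorithm.

Eligibility requires adult age (>= 18 at 1 January of the index year,
computed from birth year) and continuous SHI enrollment over the whole
look-back period (2010-2015 by default); persons who died during the index
year stay eligible, with their evidence window truncated at death.

A person is a T2D case when at least one of four criteria holds on index-year
claims:

* C1 — a non-insulin glucose-lowering agent (ATC A10B) dispensed in at
  least two distinct quarters;
* C2 — any glucose-lowering agent (ATC A10) plus at least one evidential
  E11 diagnosis (confirmed ambulatory, or hospital main/secondary);
* C3 — an A10B dispensation with a blood-glucose/HbA1c lab billing (EBM
  32025/32057/32881/32094) by the prescribing physician in the same quarter;
* C4 — evidential E11 diagnoses in at least three of four quarters.

Persons qualifying only through the drug-based criteria (C1/C3) who carry an
unspecific-diabetes diagnosis (E14) but no E11 are excluded as indeterminate
diabetes type.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .claims_model import (
    KNOWN_EBM_CODES,
    ClaimsBundle,
    PersonClaims,
    PersonRecord,
    Qualifier,
    Setting,
    quarter_of,
)
from .cvd import (
    DEFINITION_NAMES,
    ObservationWindow,
    build_definition,
    characterize,
    classify_cvd,
    classify_therapy,
)

__all__ = [
    "EligibilityDecision",
    "T2DDecision",
    "check_eligibility",
    "identify_t2d",
    "duration_category",
    "build_cohort",
    "age_band",
    "AGE_BANDS",
    "DURATION_CATEGORIES",
]

DURATION_CATEGORIES = ("incident_2015", "1y", "2y", "3y", "4y", "5plus")

#: Adult age bands used for stratified reporting.
AGE_BANDS = ("18-39", "40-59", "60-79", "80plus")


def age_band(age: int) -> str:
    if age < 18:
        return "under18"
    if age < 40:
        return "18-39"
    if age < 60:
        return "40-59"
    if age < 80:
        return "60-79"
    return "80plus"


@dataclass(frozen=True)
class EligibilityDecision:
    person_id: str
    adult: bool
    continuously_enrolled: bool
    reason: str = ""

    @property
    def eligible(self) -> bool:
        return self.adult and self.continuously_enrolled


@dataclass(frozen=True)
class T2DDecision:
    person_id: str
    is_case: bool
    criteria_met: frozenset[str]
    excluded_e14_only: bool
    first_evidence_year: Optional[int]
    duration_category: Optional[str]
    drug_only_no_diabetes_dx: bool = False  # C1/C3 case without any E11/E14 code


def check_eligibility(
    person: PersonRecord,
    as_of_year: int = 2015,
    lookback_start: dt.date = dt.date(2010, 1, 1),
) -> EligibilityDecision:
    """Adult-age and continuous-enrollment gate for the study population.

    Death during the index year does not break continuity (the enrollment
    span ends at death); death before the index year does.
    """
    adult = (as_of_year - person.birth_year) >= 18
    required_end = dt.date(as_of_year, 12, 31)
    if person.death_date is not None and person.death_date.year == as_of_year:
        required_end = person.death_date
    enrolled = (
        person.enrollment_start <= lookback_start
        and person.enrollment_end >= required_end
    )
    reasons = []
    if not adult:
        reasons.append(f"age {as_of_year - person.birth_year} under 18")
    if not enrolled:
        if person.death_date is not None and person.death_date.year < as_of_year:
            reasons.append(f"died {person.death_date} before index year")
        else:
            reasons.append(
                f"enrollment {person.enrollment_start}..{person.enrollment_end} "
                f"does not cover {lookback_start}..{required_end}"
            )
    return EligibilityDecision(
        person_id=person.person_id,
        adult=adult,
        continuously_enrolled=enrolled,
        reason="; ".join(reasons),
    )


def _evidential_diagnosis(d) -> bool:
    """Confirmed ('gesichert') ambulatory, or hospital main/secondary."""
    if d.setting is Setting.ambulatory:
        return d.qualifier is Qualifier.G
    return True


def identify_t2d(pc: PersonClaims, index_year: int = 2015) -> T2DDecision:
    """Evaluate the four T2D criteria and the E14 exclusion on one person.

    All criteria are evaluated and recorded even when an earlier one already
    qualifies the person.  For decedents only evidence on or before the
    death date counts.
    """
    person = pc.person
    death = person.death_date

    def alive_at(d: dt.date) -> bool:
        return death is None or d <= death

    rx_year = [
        r
        for r in pc.prescriptions
        if r.dispense_date.year == index_year and alive_at(r.dispense_date)
    ]
    for r in pc.prescriptions:
        if r.person_id != person.person_id:
            raise ValueError(
                f"claim for person {r.person_id} passed with person {person.person_id}"
            )

    a10b_quarters = {
        quarter_of(r.dispense_date) for r in rx_year if r.atc_code.startswith("A10B")
    }
    any_a10 = any(r.atc_code.startswith("A10") for r in rx_year)

    e11_quarters = set()
    has_e11 = False
    has_e14 = False
    for d in pc.diagnoses:
        if d.service_date.year != index_year or not alive_at(d.service_date):
            continue
        if not _evidential_diagnosis(d):
            continue
        if d.icd_code.startswith("E11"):
            has_e11 = True
            e11_quarters.add(quarter_of(d.service_date))
        elif d.icd_code.startswith("E14"):
            has_e14 = True

    lab_quarters_by_physician: dict[str, set] = {}
    for lab in pc.lab_services:
        if (
            lab.service_date.year == index_year
            and alive_at(lab.service_date)
            and lab.ebm_code in KNOWN_EBM_CODES
        ):
            lab_quarters_by_physician.setdefault(lab.physician_id, set()).add(
                quarter_of(lab.service_date)
            )

    c1 = len(a10b_quarters) >= 2
    c2 = any_a10 and has_e11
    c3 = any(
        r.atc_code.startswith("A10B")
        and quarter_of(r.dispense_date)
        in lab_quarters_by_physician.get(r.prescriber_id, set())
        for r in rx_year
    )
    c4 = len(e11_quarters) >= 3

    criteria = set()
    if c1:
        criteria.add("C1_two_quarter_A10B")
    if c2:
        criteria.add("C2_A10_plus_E11")
    if c3:
        criteria.add("C3_A10B_plus_lab_same_quarter_same_physician")
    if c4:
        criteria.add("C4_E11_three_of_four_quarters")

    drug_only = bool(criteria) and criteria <= {
        "C1_two_quarter_A10B",
        "C3_A10B_plus_lab_same_quarter_same_physician",
    }
    excluded = drug_only and has_e14 and not has_e11
    is_case = bool(criteria) and not excluded

    first_year: Optional[int] = None
    category: Optional[str] = None
    if is_case:
        first_year = _first_evidence_year(pc, index_year)
        category = duration_category(first_year, index_year)

    return T2DDecision(
        person_id=person.person_id,
        is_case=is_case,
        criteria_met=frozenset(criteria),
        excluded_e14_only=excluded,
        first_evidence_year=first_year,
        duration_category=category,
        drug_only_no_diabetes_dx=is_case and drug_only and not has_e11 and not has_e14,
    )


def _first_evidence_year(pc: PersonClaims, index_year: int) -> int:
    """Earliest look-back year with any E11 diagnosis or A10 prescription."""
    years = set()
    death = pc.person.death_date
    for d in pc.diagnoses:
        if death is not None and d.service_date > death:
            continue
        if d.icd_code.startswith("E11") and _evidential_diagnosis(d):
            years.add(d.service_date.year)
    for r in pc.prescriptions:
        if death is not None and r.dispense_date > death:
            continue
        if r.atc_code.startswith("A10"):
            years.add(r.dispense_date.year)
    in_range = [y for y in years if y <= index_year]
    return min(in_range) if in_range else index_year


def duration_category(first_evidence_year: int, index_year: int = 2015) -> str:
    """Time-since-diagnosis bucket from the earliest evidence year.

    No evidence before the index year -> incident; evidence at the start of
    the look-back -> "5plus" (left-censored; true onset may be earlier).
    """
    delta = index_year - first_evidence_year
    if delta <= 0:
        return "incident_2015"
    if delta >= 5:
        return "5plus"
    return f"{delta}y"


# ---------------------------------------------------------------------------
# Cohort table construction
# ---------------------------------------------------------------------------

def build_cohort(
    bundle: ClaimsBundle,
    index_year: int = 2015,
    windows: Optional[list[ObservationWindow]] = None,
    definitions: tuple[str, ...] = DEFINITION_NAMES,
    use_ops: bool = True,
) -> pd.DataFrame:
    """One row per person: eligibility, T2D decision, strata, CVD flags.

    CVD columns are named ``cvd_{definition}_{start}_{end}``; only eligible
    T2D cases carry CVD, characterization and therapy values.
    """
    if windows is None:
        windows = [ObservationWindow(y, index_year) for y in range(2010, index_year + 1)]
    defns = {name: build_definition(name, use_ops=use_ops) for name in definitions}

    flag_cols = [
        "hypertension",
        "lipometabolic_disorder",
        "macrovascular_event",
        "microvascular_event",
        "t2d_hospitalization",
    ] + [
        f"cvd_{name}_{w.start_year}_{w.end_year}" for name in defns for w in windows
    ]

    grouped = bundle.grouped()
    rows = []
    for pid, pc in grouped.items():
        person = pc.person
        elig = check_eligibility(person, as_of_year=index_year)
        row: dict = {
            "person_id": pid,
            "sex": person.sex.value,
            "age": index_year - person.birth_year,
            "age_band": age_band(index_year - person.birth_year),
            "adult": elig.adult,
            "continuously_enrolled": elig.continuously_enrolled,
            "eligible": elig.eligible,
            "ineligibility_reason": elig.reason,
            "is_case": False,
            "criteria_met": "",
            "excluded_e14_only": False,
            "drug_only_no_diabetes_dx": False,
            "first_evidence_year": pd.NA,
            "duration_category": "",
            "therapy_class": "",
            **{c: False for c in flag_cols},
        }
        if elig.eligible:
            dec = identify_t2d(pc, index_year=index_year)
            row.update(
                is_case=dec.is_case,
                criteria_met="|".join(sorted(dec.criteria_met)),
                excluded_e14_only=dec.excluded_e14_only,
                drug_only_no_diabetes_dx=dec.drug_only_no_diabetes_dx,
                first_evidence_year=dec.first_evidence_year
                if dec.first_evidence_year is not None
                else pd.NA,
                duration_category=dec.duration_category or "",
            )
            if dec.is_case:
                row["therapy_class"] = classify_therapy(pc, index_year).label
                ch = characterize(pc, index_year)
                row.update(
                    hypertension=ch.hypertension,
                    lipometabolic_disorder=ch.lipometabolic_disorder,
                    macrovascular_event=ch.macrovascular_event,
                    microvascular_event=ch.microvascular_event,
                    t2d_hospitalization=ch.t2d_hospitalization,
                )
                for name, defn in defns.items():
                    for w in windows:
                        flag, _ = classify_cvd(pc, defn, w)
                        row[f"cvd_{name}_{w.start_year}_{w.end_year}"] = flag
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        return pd.DataFrame(
            columns=["person_id", "sex", "age", "age_band", "adult",
                     "continuously_enrolled", "eligible", "ineligibility_reason",
                     "is_case", "criteria_met", "excluded_e14_only",
                     "drug_only_no_diabetes_dx", "first_evidence_year",
                     "duration_category", "therapy_class", *flag_cols]
        )
    for col in flag_cols:
        frame[col] = frame[col].astype(bool)
    return frame
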