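"""Eligibility gate, the four-criterion T2D algorithm, and the E14 exclusion."""

import datetime as dt
import random

import pytest

from t2d_cvd.claims_model import (
    KNOWN_EBM_CODES,
    DiagnosisRecord,
    LabServiceRecord,
    PersonClaims,
    PrescriptionRecord,
    Qualifier,
    Setting,
)
from t2d_cvd.cohort import check_eligibility, duration_category, identify_t2d

from conftest import dx, lab, make_person, person_claims, rx

D = dt.date


# ---------------------------------------------------------------------------
# Independent brute-force oracle: literal set comprehensions over quarters,
# written without reference to the implementation.
# ---------------------------------------------------------------------------

def oracle_t2d(pc: PersonClaims, year: int = 2015):
    death = pc.person.death_date
    alive = lambda d: death is None or d <= death
    q = lambda d: (d.month - 1) // 3

    rxs = [r for r in pc.prescriptions if r.dispense_date.year == year and alive(r.dispense_date)]
    good_dx = [
        d
        for d in pc.diagnoses
        if d.service_date.year == year
        and alive(d.service_date)
        and (d.setting is not Setting.ambulatory or d.qualifier is Qualifier.G)
    ]
    labs = [
        l
        for l in pc.lab_services
        if l.service_date.year == year and alive(l.service_date) and l.ebm_code in KNOWN_EBM_CODES
    ]
    e11 = [d for d in good_dx if d.icd_code.startswith("E11")]
    e14 = [d for d in good_dx if d.icd_code.startswith("E14")]

    c1 = len({q(r.dispense_date) for r in rxs if r.atc_code.startswith("A10B")}) >= 2
    c2 = any(r.atc_code.startswith("A10") for r in rxs) and bool(e11)
    c3 = any(
        r.atc_code.startswith("A10B")
        and any(
            l.physician_id == r.prescriber_id and q(l.service_date) == q(r.dispense_date)
            for l in labs
        )
        for r in rxs
    )
    c4 = len({q(d.service_date) for d in e11}) >= 3

    drug_only = (c1 or c3) and not c2 and not c4
    excluded = drug_only and bool(e14) and not e11
    return {"C1": c1, "C2": c2, "C3": c3, "C4": c4,
            "is_case": (c1 or c2 or c3 or c4) and not excluded,
            "excluded": excluded}


def random_person_claims(rng: random.Random) -> PersonClaims:
    """Randomized claim sets stressing the criterion boundaries."""
    death = D(2015, rng.randint(1, 12), rng.randint(1, 28)) if rng.random() < 0.1 else None
    person = make_person(
        pid="PX",
        birth_year=rng.randint(1920, 1996),
        end=death or D(2015, 12, 31),
        death=death,
    )
    atcs = ["A10BA02", "A10BB01", "A10AB01", "A10AE04", "C07AB02"]
    icds = ["E119", "E1190", "E149", "E109", "I10", "E780"]
    docs = ["DOC1", "DOC2"]
    pc = person_claims(person=person)
    for _ in range(rng.randint(0, 6)):
        pc.prescriptions.append(
            PrescriptionRecord("PX", rng.choice(atcs),
                               D(2015, rng.randint(1, 12), rng.randint(1, 28)),
                               rng.choice(docs))
        )
    for _ in range(rng.randint(0, 6)):
        setting = rng.choice(list(Setting))
        qual = rng.choice(list(Qualifier)) if setting is Setting.ambulatory else None
        pc.diagnoses.append(
            DiagnosisRecord("PX", rng.choice(icds), setting, qual,
                            D(rng.choice([2014, 2015]), rng.randint(1, 12), rng.randint(1, 28)))
        )
    for _ in range(rng.randint(0, 3)):
        pc.lab_services.append(
            LabServiceRecord("PX", rng.choice(["32025", "32057", "32881", "32094", "99999"]),
                             D(2015, rng.randint(1, 12), rng.randint(1, 28)),
                             rng.choice(docs))
        )
    return pc


class TestEligibility:
    def test_age_18_at_index_is_adult(self):
        assert check_eligibility(make_person(birth_year=1997)).adult

    def test_age_17_is_not(self):
        dec = check_eligibility(make_person(birth_year=1998))
        assert not dec.adult and "under 18" in dec.reason

    def test_late_enrollment_breaks_continuity(self):
        dec = check_eligibility(make_person(start=D(2011, 3, 1)))
        assert not dec.continuously_enrolled and dec.reason

    def test_death_in_index_year_keeps_eligibility(self):
        p = make_person(end=D(2015, 6, 1), death=D(2015, 6, 1))
        assert check_eligibility(p).continuously_enrolled

    def test_death_before_index_year_excludes(self):
        p = make_person(end=D(2014, 6, 1), death=D(2014, 6, 1))
        dec = check_eligibility(p)
        assert not dec.continuously_enrolled and "died" in dec.reason


class TestIdentifyT2D:
    def test_a10b_in_two_quarters_is_case(self):
        pc = person_claims(prescriptions=[rx("A10BA02", D(2015, 2, 1)), rx("A10BA02", D(2015, 8, 1))])
        dec = identify_t2d(pc)
        assert dec.is_case and dec.criteria_met == {"C1_two_quarter_A10B"}

    def test_single_a10b_plus_same_quarter_same_physician_lab(self):
        pc = person_claims(
            prescriptions=[rx("A10BA02", D(2015, 5, 10), prescriber="DOC7")],
            labs=[lab("32025", D(2015, 6, 20), physician="DOC7")],
        )
        dec = identify_t2d(pc)
        assert dec.is_case
        assert dec.criteria_met == {"C3_A10B_plus_lab_same_quarter_same_physician"}

    def test_lab_by_other_physician_does_not_qualify(self):
        pc = person_claims(
            prescriptions=[rx("A10BA02", D(2015, 5, 10), prescriber="DOC7")],
            labs=[lab("32025", D(2015, 6, 20), physician="DOC8")],
        )
        assert not identify_t2d(pc).is_case

    def test_e11_in_three_quarters_is_case(self):
        pc = person_claims(
            diagnoses=[dx("E11.9", D(2015, 1, 5)), dx("E11.9", D(2015, 5, 5)), dx("E11.9", D(2015, 11, 5))]
        )
        dec = identify_t2d(pc)
        assert dec.is_case and dec.criteria_met == {"C4_E11_three_of_four_quarters"}

    def test_one_e11_quarter_is_not_a_case(self):
        pc = person_claims(diagnoses=[dx("E11.9", D(2015, 1, 5))])
        assert not identify_t2d(pc).is_case

    def test_insulin_only_with_e14_is_not_a_case(self):
        """Insulin (A10A) fails C1; without E11 the prescriptions fail C2."""
        pc = person_claims(
            prescriptions=[rx("A10AB01", D(2015, 2, 1)), rx("A10AB01", D(2015, 8, 1))],
            diagnoses=[dx("E14.9", D(2015, 3, 1))],
        )
        dec = identify_t2d(pc)
        assert not dec.is_case and not dec.excluded_e14_only

    def test_insulin_plus_e11_is_case_via_c2(self):
        pc = person_claims(
            prescriptions=[rx("A10AB01", D(2015, 2, 1))],
            diagnoses=[dx("E11.9", D(2015, 3, 1))],
        )
        assert identify_t2d(pc).criteria_met == {"C2_A10_plus_E11"}

    def test_suspected_diagnosis_does_not_count(self):
        pc = person_claims(
            diagnoses=[
                dx("E11.9", D(2015, 1, 5), qualifier=Qualifier.V),
                dx("E11.9", D(2015, 5, 5), qualifier=Qualifier.V),
                dx("E11.9", D(2015, 11, 5), qualifier=Qualifier.V),
            ]
        )
        assert not identify_t2d(pc).is_case

    def test_evidence_after_death_ignored(self):
        p = make_person(end=D(2015, 4, 1), death=D(2015, 4, 1))
        pc = person_claims(
            person=p,
            prescriptions=[rx("A10BA02", D(2015, 2, 1)), rx("A10BA02", D(2015, 8, 1))],
        )
        # the post-mortem dispensation is discarded, leaving a single quarter
        assert not identify_t2d(pc).is_case

    def test_e14_exclusion_for_drug_only_case(self):
        pc = person_claims(
            prescriptions=[rx("A10BA02", D(2015, 2, 1)), rx("A10BA02", D(2015, 8, 1))],
            diagnoses=[dx("E14.9", D(2015, 3, 1))],
        )
        dec = identify_t2d(pc)
        assert dec.excluded_e14_only and not dec.is_case

    def test_e11_neutralizes_e14_exclusion(self):
        pc = person_claims(
            prescriptions=[rx("A10BA02", D(2015, 2, 1)), rx("A10BA02", D(2015, 8, 1))],
            diagnoses=[dx("E14.9", D(2015, 3, 1)), dx("E11.9", D(2015, 3, 2))],
        )
        dec = identify_t2d(pc)
        assert dec.is_case and not dec.excluded_e14_only

    def test_drug_only_case_without_any_diabetes_code_is_flagged(self):
        pc = person_claims(
            prescriptions=[rx("A10BA02", D(2015, 2, 1)), rx("A10BA02", D(2015, 8, 1))]
        )
        dec = identify_t2d(pc)
        assert dec.is_case and dec.drug_only_no_diabetes_dx

    def test_foreign_claims_rejected(self):
        pc = person_claims(prescriptions=[rx("A10BA02", D(2015, 2, 1), pid="OTHER")])
        with pytest.raises(ValueError, match="OTHER"):
            identify_t2d(pc)

    def test_monotonicity_single_exception(self):
        """Adding rows never un-cases a person, except E14 onto a drug-only case."""
        base = person_claims(
            prescriptions=[rx("A10BA02", D(2015, 2, 1)), rx("A10BA02", D(2015, 8, 1))]
        )
        assert identify_t2d(base).is_case
        base.diagnoses.append(dx("E14.9", D(2015, 3, 1)))
        assert not identify_t2d(base).is_case  # the one documented exception
        base.diagnoses.append(dx("E11.9", D(2015, 4, 1)))
        assert identify_t2d(base).is_case  # and it is reversible by E11

    def test_randomized_add_row_monotonicity(self):
        rng = random.Random(7)
        for _ in range(300):
            pc = random_person_claims(rng)
            before = identify_t2d(pc)
            extra = random_person_claims(rng)
            pc.diagnoses += [d for d in extra.diagnoses if not d.icd_code.startswith("E14")]
            pc.prescriptions += extra.prescriptions
            pc.lab_services += extra.lab_services
            after = identify_t2d(pc)
            if before.is_case:
                assert after.is_case


class TestOracleEquivalence:
    def test_matches_brute_force_on_randomized_persons(self):
        rng = random.Random(123)
        for _ in range(500):
            pc = random_person_claims(rng)
            dec = identify_t2d(pc)
            ora = oracle_t2d(pc)
            got = {
                "C1": "C1_two_quarter_A10B" in dec.criteria_met,
                "C2": "C2_A10_plus_E11" in dec.criteria_met,
                "C3": "C3_A10B_plus_lab_same_quarter_same_physician" in dec.criteria_met,
                "C4": "C4_E11_three_of_four_quarters" in dec.criteria_met,
                "is_case": dec.is_case,
                "excluded": dec.excluded_e14_only,
            }
            assert got == ora, f"disagreement on {pc}"


class TestDuration:
    @pytest.mark.parametrize(
        "first_year, expected",
        [(2010, "5plus"), (2009, "5plus"), (2011, "4y"), (2014, "1y"), (2015, "incident_2015")],
    )
    def test_categories(self, first_year, expected):
        assert duration_category(first_year, 2015) == expected

    def test_first_evidence_drives_category(self):
        pc = person_claims(
            prescriptions=[rx("A10BA02", D(2014, 6, 1)), rx("A10BA02", D(2015, 2, 1)),
                           rx("A10BA02", D(2015, 8, 1))]
        )
        dec = identify_t2d(pc)
        assert dec.first_evidence_year == 2014 and dec.duration_category == "1y"

    def test_no_prior_evidence_is_incident(self):
        pc = person_claims(
            prescriptions=[rx("A10BA02", D(2015, 2, 1)), rx("A10BA02", D(2015, 8, 1))]
        )
        assert identify_t2d(pc).duration_category == "incident_2015"
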