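"""Code-set matching, nested CVD definitions, window classification, therapy classes."""

import datetime as dt

import pytest

from t2d_cvd.claims_model import Setting
from t2d_cvd.cvd import (
    CodeSet,
    ObservationWindow,
    build_definition,
    characterize,
    classify_cvd,
    classify_therapy,
    load_code_universe,
    match,
)

from conftest import dx, make_person, person_claims, proc, rx

D = dt.date
W_FULL = ObservationWindow(2010, 2015)

NARROW_ICD = build_definition("narrow").icd_sets[0]


def oracle_narrow_icd(code: str) -> bool:
    """Rule-as-written restatement of the narrow ICD list, coded literally."""
    if code.startswith(("I253", "I254", "I2510", "I2519")):
        return False
    return code.startswith(
        ("I63", "I64", "I200", "I21", "I22", "I24", "I25", "I739", "I702")
    )


class TestMatch:
    @pytest.mark.parametrize(
        "code, expected",
        [
            ("I2511", True),   # I25 included, only .3/.4/.10/.19 excluded
            ("I2510", False),
            ("I2519", False),
            ("I253", False),
            ("I639", True),
            ("I650", False),
            ("I200", True),
            ("I201", False),   # only I20.0 in the narrow list
            ("I739", True),
            ("I738", False),
            ("I7020", True),
        ],
    )
    def test_narrow_examples(self, code, expected):
        assert match(code, NARROW_ICD) is expected

    def test_empty_set_matches_nothing(self):
        empty = CodeSet("empty", "ICD", frozenset())
        assert not match("I21", empty)

    def test_system_mismatch_raises(self):
        with pytest.raises(ValueError, match="system"):
            match("5-361", NARROW_ICD, system="OPS")

    def test_exclude_must_extend_include(self):
        with pytest.raises(ValueError, match="extends no include"):
            CodeSet("bad", "ICD", frozenset({"I21"}), frozenset({"I50"}))

    def test_enumeration_equals_oracle_on_universe(self):
        universe = load_code_universe()
        icd_codes = [c for s, c in universe if s == "ICD"]
        assert len(icd_codes) > 1000
        for code in icd_codes:
            assert match(code, NARROW_ICD) == oracle_narrow_icd(code), code


class TestDefinitions:
    def test_narrow_includes_bypass_stent_prefix(self):
        ops = build_definition("narrow").ops_sets[0]
        assert match("8-840", ops) and match("8-841", ops) and match("8-837", ops)
        assert not match("8-850", ops)

    def test_chf_only_in_narrow_chf_and_wide(self):
        assert not build_definition("narrow").matches_icd("I501")
        assert build_definition("narrow_chf").matches_icd("I501")
        assert build_definition("wide").matches_icd("I501")

    def test_hemorrhage_only_in_wide(self):
        assert not build_definition("narrow_chf").matches_icd("I609")
        assert build_definition("wide").matches_icd("I609")

    def test_wide_drops_ischemic_exclusions(self):
        assert not build_definition("narrow").matches_icd("I2510")
        assert build_definition("wide").matches_icd("I2510")

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_definition("broadest")

    def test_nesting_on_code_universe(self):
        """Coverage sets are strictly nested: narrow < narrow+CHF < wide."""
        universe = load_code_universe()
        covered = {}
        for name in ("narrow", "narrow_chf", "wide"):
            defn = build_definition(name)
            covered[name] = {
                (s, c)
                for s, c in universe
                if (s == "ICD" and defn.matches_icd(c)) or (s == "OPS" and defn.matches_ops(c))
            }
        assert covered["narrow"] < covered["narrow_chf"] < covered["wide"]


class TestClassifyCVD:
    def test_hospital_diagnosis_in_window(self):
        pc = person_claims(diagnoses=[dx("I21.9", D(2012, 5, 1), setting=Setting.hospital_main)])
        flag, hit = classify_cvd(pc, build_definition("narrow"), W_FULL)
        assert flag and hit.code == "I219" and hit.date == D(2012, 5, 1)

    def test_event_outside_window(self):
        pc = person_claims(diagnoses=[dx("I21.9", D(2012, 5, 1), setting=Setting.hospital_main)])
        flag, hit = classify_cvd(pc, build_definition("narrow"), ObservationWindow(2013, 2015))
        assert not flag and hit is None

    def test_ops_ignored_when_disabled(self):
        pc = person_claims(procedures=[proc("5-361", D(2011, 3, 3))])
        assert classify_cvd(pc, build_definition("narrow", use_ops=True), W_FULL)[0]
        assert not classify_cvd(pc, build_definition("narrow", use_ops=False), W_FULL)[0]

    def test_suspected_ambulatory_diagnosis_ignored(self):
        from t2d_cvd.claims_model import Qualifier

        pc = person_claims(diagnoses=[dx("I21.9", D(2012, 5, 1), qualifier=Qualifier.V)])
        assert not classify_cvd(pc, build_definition("narrow"), W_FULL)[0]

    def test_earliest_hit_returned(self):
        pc = person_claims(
            diagnoses=[dx("I21.9", D(2014, 5, 1), setting=Setting.hospital_main)],
            procedures=[proc("5-361", D(2011, 3, 3))],
        )
        _, hit = classify_cvd(pc, build_definition("narrow"), W_FULL)
        assert hit.kind == "procedure" and hit.date == D(2011, 3, 3)

    def test_definition_and_window_monotonicity(self, cohort_20k):
        """Broader definitions and longer windows can only add positives."""
        cohort, _ = cohort_20k
        cases = cohort[cohort["is_case"]]
        for y in range(2010, 2016):
            narrow = cases[f"cvd_narrow_{y}_2015"]
            chf = cases[f"cvd_narrow_chf_{y}_2015"]
            wide = cases[f"cvd_wide_{y}_2015"]
            assert (narrow <= chf).all() and (chf <= wide).all()
        for name in ("narrow", "narrow_chf", "wide"):
            for y in range(2011, 2016):
                longer = cases[f"cvd_{name}_{y - 1}_2015"]
                shorter = cases[f"cvd_{name}_{y}_2015"]
                assert (shorter <= longer).all()


class TestCharacterize:
    def test_ambulatory_hypertension_counts(self):
        pc = person_claims(diagnoses=[dx("I10", D(2015, 2, 1))])
        assert characterize(pc).hypertension

    def test_macrovascular_requires_hospitalization(self):
        ambulatory = person_claims(diagnoses=[dx("I21.9", D(2015, 2, 1))])
        hospital = person_claims(
            diagnoses=[dx("I21.9", D(2015, 2, 1), setting=Setting.hospital_secondary)]
        )
        assert not characterize(ambulatory).macrovascular_event
        assert characterize(hospital).macrovascular_event

    def test_amputation_procedure_is_microvascular(self):
        pc = person_claims(procedures=[proc("5-864", D(2015, 7, 1))])
        assert characterize(pc).microvascular_event

    def test_t2d_hospitalization_needs_main_diagnosis(self):
        secondary = person_claims(
            diagnoses=[dx("E11.9", D(2015, 2, 1), setting=Setting.hospital_secondary)]
        )
        main = person_claims(
            diagnoses=[dx("E11.9", D(2015, 2, 1), setting=Setting.hospital_main)]
        )
        assert not characterize(secondary).t2d_hospitalization
        assert characterize(main).t2d_hospitalization

    def test_prior_year_events_do_not_count(self):
        pc = person_claims(diagnoses=[dx("I10", D(2014, 2, 1))])
        assert not characterize(pc).hypertension


class TestTherapy:
    @pytest.mark.parametrize(
        "codes, insulin_expected, label",
        [
            ((), False, "none"),
            (("A10BA02",), False, "metformin_mono"),
            (("A10BB01",), False, "sulfonylurea_mono"),
            (("A10BA02", "A10BB01"), False, "dual_noninsulin"),
            (("A10BD02",), False, "dual_noninsulin"),  # fixed combination expands
            (("A10BA02", "A10BB01", "A10BH01"), False, "triple_plus_noninsulin"),
            (("A10AB01",), True, "insulin_only"),
            (("A10AB01", "A10BA02"), True, "insulin_plus_noninsulin"),
            (("A10BZ99",), False, "other_noninsulin_mono"),  # unmapped subclass
        ],
    )
    def test_labels(self, codes, insulin_expected, label):
        pc = person_claims(prescriptions=[rx(c, D(2015, 3, 1)) for c in codes])
        cls = classify_therapy(pc)
        assert cls.label == label and cls.insulin is insulin_expected

    def test_metformin_su_subflag(self):
        pc = person_claims(
            prescriptions=[rx("A10BA02", D(2015, 3, 1)), rx("A10BB01", D(2015, 4, 1))]
        )
        cls = classify_therapy(pc)
        assert cls.metformin_su and not cls.metformin_dpp4

    def test_non_index_year_prescriptions_ignored(self):
        pc = person_claims(prescriptions=[rx("A10BA02", D(2014, 3, 1))])
        assert classify_therapy(pc).label == "none"

    def test_classes_partition_cohort(self, cohort_20k):
        from t2d_cvd.cvd import THERAPY_LABELS

        cohort, _ = cohort_20k
        cases = cohort[cohort["is_case"]]
        assert set(cases["therapy_class"]) <= set(THERAPY_LABELS)
        assert (cases["therapy_class"] != "").all()
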