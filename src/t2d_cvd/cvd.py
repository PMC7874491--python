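"""Executable cardiovascular-disease definitions over ICD-10-GM and OPS codes.

Three nested definitions are shipped:

* ``narrow`` — the cardiovascular-outcome-trial translation: stroke
  (I63/I64), angina pectoris and ischemic heart disease (I20.0, I21-I22,
  I24-I25 excluding I25.3/.4/.10/.19), peripheral arterial occlusive disease
  (I73.9, I70.2x), coronary revascularization (OPS 5-361/5-362/5-363) and
  bypass/stent procedures (OPS 8-836/8-837/8-84x).
* ``narrow_chf`` — narrow plus chronic heart failure (I50).
* ``wide`` — narrow_chf plus intracranial hemorrhage (I60-I62) and all
  ischemic heart disease codes (I20-I25, exclusions dropped).

Matching is prefix-based with exclusion overriding inclusion, mirroring how
code lists in claims studies are written ("I25 excluding I25.3").
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

from .claims_model import (
    PersonClaims,
    Qualifier,
    Setting,
    normalize_code,
)

__all__ = [
    "CodeSet",
    "CVDDefinition",
    "ObservationWindow",
    "CVDHit",
    "match",
    "build_definition",
    "classify_cvd",
    "characterize",
    "Characterization",
    "DEFINITION_NAMES",
]

DEFINITION_NAMES = ("narrow", "narrow_chf", "wide")


def load_code_universe() -> list[tuple[str, str]]:
    """Bundled synthetic (system, code) universe for enumeration checks.

    A plausible slice of the ICD-10-GM circulatory/metabolic chapters and
    the relevant OPS procedure families, shipped as plain text.
    """
    from importlib.resources import files

    out = []
    for line in files("t2d_cvd.data").joinpath("code_universe.txt").read_text().splitlines():
        system, _, code = line.strip().partition(" ")
        if code:
            out.append((system, code))
    return out


@dataclass(frozen=True)
class CodeSet:
    """Named prefix-inclusion/exclusion rule set over one coding system."""

    name: str
    system: str  # "ICD" or "OPS"
    include_prefixes: frozenset[str]
    exclude_prefixes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        inc = frozenset(normalize_code(c, self.system) for c in self.include_prefixes)
        exc = frozenset(normalize_code(c, self.system) for c in self.exclude_prefixes)
        object.__setattr__(self, "include_prefixes", inc)
        object.__setattr__(self, "exclude_prefixes", exc)
        if inc & exc:
            raise ValueError(f"code set {self.name}: include/exclude overlap")
        for e in exc:
            if not any(e.startswith(i) for i in inc):
                raise ValueError(
                    f"code set {self.name}: exclude prefix {e} extends no include prefix"
                )


def match(code: str, cs: CodeSet, system: Optional[str] = None) -> bool:
    """True iff a normalized code extends an include prefix and no exclude prefix.

    Exclusion overrides inclusion regardless of prefix length order.
    """
    if system is not None and system != cs.system:
        raise ValueError(f"system mismatch: code is {system}, set {cs.name} is {cs.system}")
    if not any(code.startswith(p) for p in cs.include_prefixes):
        return False
    return not any(code.startswith(p) for p in cs.exclude_prefixes)


@dataclass(frozen=True)
class CVDDefinition:
    name: str
    icd_sets: tuple[CodeSet, ...]
    ops_sets: tuple[CodeSet, ...]
    use_ops: bool = True

    def matches_icd(self, code: str) -> bool:
        return any(match(code, cs) for cs in self.icd_sets)

    def matches_ops(self, code: str) -> bool:
        return self.use_ops and any(match(code, cs) for cs in self.ops_sets)


_NARROW_ICD = CodeSet(
    name="cvd_narrow_icd",
    system="ICD",
    include_prefixes=frozenset(
        {"I63", "I64", "I200", "I21", "I22", "I24", "I25", "I739", "I702"}
    ),
    exclude_prefixes=frozenset({"I253", "I254", "I2510", "I2519"}),
)

#: Revascularization and bypass/stent procedures; 8-84 covers the 8-84x children.
_NARROW_OPS = CodeSet(
    name="cvd_narrow_ops",
    system="OPS",
    include_prefixes=frozenset({"5-361", "5-362", "5-363", "8-836", "8-837", "8-84"}),
)

_CHF_ICD = CodeSet(name="chf_icd", system="ICD", include_prefixes=frozenset({"I50"}))

_WIDE_EXTRA_ICD = CodeSet(
    name="cvd_wide_extra_icd",
    system="ICD",
    # intracranial hemorrhage I60-I62 (I63/I64 already in narrow) and
    # ischemic heart disease I20-I25 with the narrow exclusions dropped
    include_prefixes=frozenset({"I60", "I61", "I62", "I20", "I23", "I25"}),
)


def build_definition(name: str, use_ops: bool = True) -> CVDDefinition:
    """Return one of the frozen nested CVD definitions.

    ``use_ops=False`` reproduces the sensitivity analysis that drops
    procedure codes from the selection criteria.
    """
    if name == "narrow":
        icd: tuple[CodeSet, ...] = (_NARROW_ICD,)
    elif name == "narrow_chf":
        icd = (_NARROW_ICD, _CHF_ICD)
    elif name == "wide":
        icd = (_NARROW_ICD, _CHF_ICD, _WIDE_EXTRA_ICD)
    else:
        raise ValueError(f"unknown CVD definition {name!r}; expected one of {DEFINITION_NAMES}")
    return CVDDefinition(name=name, icd_sets=icd, ops_sets=(_NARROW_OPS,), use_ops=use_ops)


@dataclass(frozen=True, order=True)
class ObservationWindow:
    """Inclusive calendar-year interval [start_year, end_year]."""

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("start_year after end_year")

    def contains(self, d: dt.date) -> bool:
        return self.start_year <= d.year <= self.end_year

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    def __str__(self) -> str:
        if self.start_year == self.end_year:
            return str(self.start_year)
        return f"{self.start_year}-{self.end_year}"


@dataclass(frozen=True)
class CVDHit:
    """Audit record of the first event that satisfied a CVD definition."""

    kind: str  # "diagnosis" or "procedure"
    code: str
    date: dt.date


def _diagnosis_counts(diag) -> bool:
    """A diagnosis is evidential when confirmed ambulatory or any hospital setting."""
    if diag.setting is Setting.ambulatory:
        return diag.qualifier is Qualifier.G
    return True


def classify_cvd(
    pc: PersonClaims, defn: CVDDefinition, window: ObservationWindow
) -> tuple[bool, Optional[CVDHit]]:
    """Flag a person as CVD-prevalent within an observation window.

    A person qualifies with at least one evidential diagnosis matching an
    ICD set, or — when the definition uses procedures — one matching OPS
    procedure, dated inside the window.  Returns the earliest qualifying
    event for audit.
    """
    best: Optional[CVDHit] = None
    for diag in pc.diagnoses:
        if not window.contains(diag.service_date) or not _diagnosis_counts(diag):
            continue
        if defn.matches_icd(diag.icd_code):
            if best is None or diag.service_date < best.date:
                best = CVDHit("diagnosis", diag.icd_code, diag.service_date)
    if defn.use_ops:
        for proc in pc.procedures:
            if not window.contains(proc.service_date):
                continue
            if defn.matches_ops(proc.ops_code):
                if best is None or proc.service_date < best.date:
                    best = CVDHit("procedure", proc.ops_code, proc.service_date)
    return best is not None, best


# ---------------------------------------------------------------------------
# Cohort characterization (comorbidity and event flags, index year)
# ---------------------------------------------------------------------------

_MACRO_ICD = CodeSet(
    name="macrovascular_icd",
    system="ICD",
    include_prefixes=frozenset({"I60", "I61", "I62", "I63", "I64", "I21", "I50", "I739", "I20"}),
)
_MACRO_OPS = CodeSet(
    name="macrovascular_ops",
    system="OPS",
    include_prefixes=frozenset({"5-361", "5-362", "5-363", "8-836", "8-837", "8-84"}),
)
_MICRO_ICD = CodeSet(name="microvascular_icd", system="ICD", include_prefixes=frozenset({"N185"}))
_MICRO_OPS = CodeSet(
    name="microvascular_ops",
    system="OPS",
    include_prefixes=frozenset({"5-864", "5-865", "5-158", "5-159"}),
)


@dataclass(frozen=True)
class Characterization:
    hypertension: bool
    lipometabolic_disorder: bool
    macrovascular_event: bool
    microvascular_event: bool
    t2d_hospitalization: bool


def characterize(pc: PersonClaims, index_year: int = 2015) -> Characterization:
    """Index-year comorbidity and event flags.

    Hypertension (I10) and lipometabolic disorder (E78) count in any
    evidential setting; macro-/microvascular events require a hospital
    setting (hospitalization-defined events); T2D-related hospitalization
    requires E11 as hospital main diagnosis.
    """
    hyp = lip = macro = micro = t2d_hosp = False
    for d in pc.diagnoses:
        if d.service_date.year != index_year or not _diagnosis_counts(d):
            continue
        if d.icd_code.startswith("I10"):
            hyp = True
        if d.icd_code.startswith("E78"):
            lip = True
        if d.setting is not Setting.ambulatory:
            if match(d.icd_code, _MACRO_ICD):
                macro = True
            if match(d.icd_code, _MICRO_ICD):
                micro = True
            if d.setting is Setting.hospital_main and d.icd_code.startswith("E11"):
                t2d_hosp = True
    for p in pc.procedures:
        if p.service_date.year != index_year:
            continue
        if match(p.ops_code, _MACRO_OPS):
            macro = True
        if match(p.ops_code, _MICRO_OPS):
            micro = True
    return Characterization(hyp, lip, macro, micro, t2d_hosp)


# ---------------------------------------------------------------------------
# Glucose-lowering therapy classification
# ---------------------------------------------------------------------------

#: Non-insulin glucose-lowering drug subclasses by ATC prefix.  Fixed
#: combinations (A10BD) are expanded to their component subclasses.  The
#: mapping is intentionally a plain table so users can override it.
ATC_SUBCLASS_MAP: dict[str, str] = {
    "A10BA": "metformin",
    "A10BB": "sulfonylurea",
    "A10BH": "dpp4",
    "A10BJ": "glp1",
    "A10BK": "sglt2",
    "A10BX02": "glinide",
    "A10BX03": "glinide",
    "A10BF": "glucosidase",
}

#: A10BD fixed-combination codes expanded to component subclasses.
ATC_COMBINATION_MAP: dict[str, tuple[str, ...]] = {
    "A10BD01": ("metformin", "other"),
    "A10BD02": ("metformin", "sulfonylurea"),
    "A10BD03": ("metformin", "other"),
    "A10BD05": ("metformin", "other"),
    "A10BD07": ("metformin", "dpp4"),
    "A10BD08": ("metformin", "dpp4"),
    "A10BD09": ("metformin", "dpp4"),
    "A10BD10": ("metformin", "dpp4"),
    "A10BD11": ("metformin", "dpp4"),
    "A10BD13": ("metformin", "dpp4"),
    "A10BD15": ("metformin", "sglt2"),
    "A10BD16": ("metformin", "sglt2"),
    "A10BD19": ("metformin", "sglt2"),
    "A10BD20": ("metformin", "sglt2"),
    "A10BD21": ("dpp4", "sglt2"),
    "A10BD23": ("metformin", "sglt2"),
    "A10BD25": ("metformin", "sglt2", "dpp4"),
}

_MONO_LABELS = {
    "metformin": "metformin_mono",
    "sulfonylurea": "sulfonylurea_mono",
    "dpp4": "dpp4_mono",
    "glp1": "glp1_mono",
    "sglt2": "sglt2_mono",
    "glinide": "glinide_mono",
    "glucosidase": "glucosidase_mono",
    "other": "other_noninsulin_mono",
}

THERAPY_LABELS = (
    "none",
    "metformin_mono",
    "sulfonylurea_mono",
    "dpp4_mono",
    "glp1_mono",
    "sglt2_mono",
    "glinide_mono",
    "glucosidase_mono",
    "other_noninsulin_mono",
    "dual_noninsulin",
    "triple_plus_noninsulin",
    "insulin_only",
    "insulin_plus_noninsulin",
)


@dataclass(frozen=True)
class TherapyClass:
    label: str
    subclasses: frozenset[str]
    insulin: bool
    metformin_su: bool = False
    metformin_dpp4: bool = False


def _subclasses_of(atc: str) -> tuple[str, ...]:
    if atc.startswith("A10BD"):
        return ATC_COMBINATION_MAP.get(atc[:7], ("metformin", "other"))
    for prefix in ("A10BX02", "A10BX03"):
        if atc.startswith(prefix):
            return (ATC_SUBCLASS_MAP[prefix],)
    sub = ATC_SUBCLASS_MAP.get(atc[:5])
    if sub is not None:
        return (sub,)
    return ("other",)


def classify_therapy(pc: PersonClaims, index_year: int = 2015) -> TherapyClass:
    """Assign one glucose-lowering therapy class from index-year prescriptions.

    The class is derived from the set of distinct non-insulin subclasses
    dispensed plus the presence of insulin (A10A); classes partition the
    cohort.  Unmapped A10B codes count as one "other" non-insulin subclass.
    """
    insulin = False
    subclasses: set[str] = set()
    for rx in pc.prescriptions:
        if rx.dispense_date.year != index_year or not rx.atc_code.startswith("A10"):
            continue
        if rx.atc_code.startswith("A10A"):
            insulin = True
        else:
            subclasses.update(_subclasses_of(rx.atc_code))
    n = len(subclasses)
    met_su = {"metformin", "sulfonylurea"} <= subclasses and n == 2
    met_dpp4 = {"metformin", "dpp4"} <= subclasses and n == 2
    if insulin:
        label = "insulin_plus_noninsulin" if n else "insulin_only"
    elif n == 0:
        label = "none"
    elif n == 1:
        label = _MONO_LABELS[next(iter(subclasses))]
    elif n == 2:
        label = "dual_noninsulin"
    else:
        label = "triple_plus_noninsulin"
    return TherapyClass(
        label=label,
        subclasses=frozenset(subclasses),
        insulin=insulin,
        metformin_su=met_su and not insulin,
        metformin_dpp4=met_dpp4 and not insulin,
    )
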