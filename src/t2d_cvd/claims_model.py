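"""Domain types and I/O for German statutory health insurance (SHI) claims extracts.

The interchange schema is one delimited table per record stream — persons,
diagnoses (ambulatory and hospital), prescriptions, hospital procedures, and
lab-billing services — with ISO-8601 dates and a header row.  Codes are stored
dot-free internally (``I25.10`` -> ``I2510``); dotted forms are accepted on
input.  OPS procedure codes keep their first hyphen (``5-361``).
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
import re
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Setting",
    "Qualifier",
    "PersonRecord",
    "DiagnosisRecord",
    "PrescriptionRecord",
    "ProcedureRecord",
    "LabServiceRecord",
    "Quarter",
    "ClaimsBundle",
    "PersonClaims",
    "ClaimsValidationError",
    "normalize_code",
    "quarter_of",
    "read_claims",
    "write_claims",
    "KNOWN_EBM_CODES",
]

#: EBM billing codes for blood glucose / HbA1c determinations.
KNOWN_EBM_CODES = frozenset({"32025", "32057", "32881", "32094"})


class ClaimsValidationError(ValueError):
    """Raised when a record or file violates the claims schema."""


class Sex(str, Enum):
    female = "female"
    male = "male"


class Setting(str, Enum):
    ambulatory = "ambulatory"
    hospital_main = "hospital_main"
    hospital_secondary = "hospital_secondary"


class Qualifier(str, Enum):
    """Ambulatory diagnosis certainty qualifier (German outpatient coding).

    G = confirmed ("gesichert"), V = suspected, A = excluded, Z = status post.
    """

    G = "G"
    V = "V"
    A = "A"
    Z = "Z"


_ICD_RE = re.compile(r"^[A-Z]\d{2,5}[A-Z]?$")
_OPS_RE = re.compile(r"^\d-\d{2,4}[a-z0-9]{0,2}$")
_ATC_RE = re.compile(r"^[A-Z][0-9A-Z]{0,6}$")


def normalize_code(raw: str, system: str) -> str:
    """Normalize a medical code for prefix comparison.

    ICD-10-GM codes are uppercased and stripped of dots (``I25.10`` ->
    ``I2510``).  OPS codes keep the first hyphen and lose dots
    (``5-361.0`` -> ``5-3610``); en-dashes are accepted as hyphens.  ATC
    codes are uppercased.  Idempotent.

    Raises
    ------
    ClaimsValidationError
        If the string is empty or does not match the system's code shape.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ClaimsValidationError(f"empty {system} code")
    code = raw.strip().replace("–", "-").replace(".", "")
    if system == "ICD":
        code = code.upper()
        if not _ICD_RE.match(code):
            raise ClaimsValidationError(f"illegal ICD-10 code {raw!r}")
    elif system == "OPS":
        # keep the first hyphen only; suffix letters in OPS are lower case
        head, _, tail = code.partition("-")
        code = head + "-" + tail.replace("-", "") if tail else head
        if not _OPS_RE.match(code):
            raise ClaimsValidationError(f"illegal OPS code {raw!r}")
    elif system == "ATC":
        code = code.upper()
        if not _ATC_RE.match(code):
            raise ClaimsValidationError(f"illegal ATC code {raw!r}")
    else:
        raise ClaimsValidationError(f"unknown coding system {system!r}")
    return code


@dataclass(frozen=True, order=True)
class Quarter:
    """Calendar quarter: Q1 = Jan-Mar ... Q4 = Oct-Dec."""

    year: int
    index: int

    def __post_init__(self) -> None:
        if self.index not in (1, 2, 3, 4):
            raise ValueError(f"quarter index must be 1..4, got {self.index}")

    @property
    def start(self) -> dt.date:
        return dt.date(self.year, 3 * (self.index - 1) + 1, 1)

    @property
    def end(self) -> dt.date:
        if self.index == 4:
            return dt.date(self.year, 12, 31)
        return dt.date(self.year, 3 * self.index + 1, 1) - dt.timedelta(days=1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.year}Q{self.index}"


def quarter_of(d: dt.date) -> Quarter:
    """Map a date to its calendar quarter."""
    return Quarter(d.year, (d.month - 1) // 3 + 1)


@dataclass(frozen=True)
class PersonRecord:
    person_id: str
    sex: Sex
    birth_year: int
    enrollment_start: dt.date
    enrollment_end: dt.date
    death_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.enrollment_start > self.enrollment_end:
            raise ClaimsValidationError(
                f"person {self.person_id}: enrollment_start after enrollment_end"
            )
        if self.death_date is not None and self.death_date != self.enrollment_end:
            raise ClaimsValidationError(
                f"person {self.person_id}: death_date must equal enrollment_end"
            )
        if self.birth_year >= self.enrollment_start.year:
            raise ClaimsValidationError(
                f"person {self.person_id}: birth_year {self.birth_year} not before "
                f"enrollment start {self.enrollment_start}"
            )


@dataclass(frozen=True)
class DiagnosisRecord:
    person_id: str
    icd_code: str
    setting: Setting
    qualifier: Optional[Qualifier]
    service_date: dt.date

    def __post_init__(self) -> None:
        object.__setattr__(self, "icd_code", normalize_code(self.icd_code, "ICD"))
        if (self.setting is Setting.ambulatory) != (self.qualifier is not None):
            raise ClaimsValidationError(
                f"person {self.person_id}: qualifier present iff setting is "
                f"ambulatory (got setting={self.setting.value}, "
                f"qualifier={getattr(self.qualifier, 'value', None)})"
            )


@dataclass(frozen=True)
class PrescriptionRecord:
    person_id: str
    atc_code: str
    dispense_date: dt.date
    prescriber_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "atc_code", normalize_code(self.atc_code, "ATC"))


@dataclass(frozen=True)
class ProcedureRecord:
    person_id: str
    ops_code: str
    service_date: dt.date

    def __post_init__(self) -> None:
        object.__setattr__(self, "ops_code", normalize_code(self.ops_code, "OPS"))


@dataclass(frozen=True)
class LabServiceRecord:
    person_id: str
    ebm_code: str
    service_date: dt.date
    physician_id: str

    def __post_init__(self) -> None:
        if not str(self.ebm_code).strip():
            raise ClaimsValidationError(f"person {self.person_id}: empty EBM code")
        object.__setattr__(self, "ebm_code", str(self.ebm_code).strip())
        if self.ebm_code not in KNOWN_EBM_CODES:
            log.debug("unknown EBM code %s (person %s)", self.ebm_code, self.person_id)

    @property
    def known(self) -> bool:
        return self.ebm_code in KNOWN_EBM_CODES


@dataclass
class PersonClaims:
    """All claim records of one person, the unit consumed by the phenotyping rules."""

    person: PersonRecord
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    prescriptions: list[PrescriptionRecord] = field(default_factory=list)
    procedures: list[ProcedureRecord] = field(default_factory=list)
    lab_services: list[LabServiceRecord] = field(default_factory=list)


@dataclass
class ClaimsBundle:
    """In-memory claims extract: one record list per stream, keyed by person."""

    persons: list[PersonRecord] = field(default_factory=list)
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    prescriptions: list[PrescriptionRecord] = field(default_factory=list)
    procedures: list[ProcedureRecord] = field(default_factory=list)
    lab_services: list[LabServiceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.persons)

    def grouped(self) -> dict[str, PersonClaims]:
        """Bucket every claim row under its person, in input order."""
        out: dict[str, PersonClaims] = {
            p.person_id: PersonClaims(person=p) for p in self.persons
        }
        for rec in self.diagnoses:
            if rec.person_id in out:
                out[rec.person_id].diagnoses.append(rec)
        for rec in self.prescriptions:
            if rec.person_id in out:
                out[rec.person_id].prescriptions.append(rec)
        for rec in self.procedures:
            if rec.person_id in out:
                out[rec.person_id].procedures.append(rec)
        for rec in self.lab_services:
            if rec.person_id in out:
                out[rec.person_id].lab_services.append(rec)
        return out


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

FILE_NAMES = {
    "persons": "persons.csv",
    "diagnoses": "diagnoses.csv",
    "prescriptions": "prescriptions.csv",
    "procedures": "procedures.csv",
    "lab_services": "lab_services.csv",
}

_COLUMNS = {
    "persons": ["person_id", "sex", "birth_year", "enrollment_start", "enrollment_end", "death_date"],
    "diagnoses": ["person_id", "icd_code", "setting", "qualifier", "service_date"],
    "prescriptions": ["person_id", "atc_code", "dispense_date", "prescriber_id"],
    "procedures": ["person_id", "ops_code", "service_date"],
    "lab_services": ["person_id", "ebm_code", "service_date", "physician_id"],
}


def _parse_date(value: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError as exc:
        raise ClaimsValidationError(f"{where}: unparseable date {value!r}") from exc


def _sniff_reader(path: Path):
    text = path.read_text()
    try:
        dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t;")
    except (csv.Error, IndexError):
        dialect = csv.excel
    return csv.DictReader(text.splitlines(), dialect=dialect)


def _require_columns(reader: csv.DictReader, table: str, path: Path) -> None:
    missing = [c for c in _COLUMNS[table] if c not in (reader.fieldnames or [])]
    if missing:
        raise ClaimsValidationError(
            f"{path}: missing column(s) {missing} in {table} table"
        )


def read_claims(directory: str | Path) -> ClaimsBundle:
    """Read a claims bundle from a directory of delimited tables.

    Comma, tab and semicolon delimiters are auto-detected; codes are
    normalized on read.  Errors carry file, line and column context.
    """
    directory = Path(directory)
    bundle = ClaimsBundle()

    path = directory / FILE_NAMES["persons"]
    reader = _sniff_reader(path)
    _require_columns(reader, "persons", path)
    for i, row in enumerate(reader, start=2):
        where = f"{path}:{i}"
        try:
            death = row.get("death_date") or ""
            bundle.persons.append(
                PersonRecord(
                    person_id=row["person_id"],
                    sex=Sex(row["sex"]),
                    birth_year=int(row["birth_year"]),
                    enrollment_start=_parse_date(row["enrollment_start"], where),
                    enrollment_end=_parse_date(row["enrollment_end"], where),
                    death_date=_parse_date(death, where) if death else None,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ClaimsValidationError(f"{where}: {exc}") from exc
    if not bundle.persons:
        log.warning("%s: empty person table", path)

    path = directory / FILE_NAMES["diagnoses"]
    reader = _sniff_reader(path)
    _require_columns(reader, "diagnoses", path)
    for i, row in enumerate(reader, start=2):
        where = f"{path}:{i} (column qualifier/setting)"
        try:
            qual = row.get("qualifier") or ""
            bundle.diagnoses.append(
                DiagnosisRecord(
                    person_id=row["person_id"],
                    icd_code=row["icd_code"],
                    setting=Setting(row["setting"]),
                    qualifier=Qualifier(qual) if qual else None,
                    service_date=_parse_date(row["service_date"], where),
                )
            )
        except ValueError as exc:
            raise ClaimsValidationError(f"{where}: {exc}") from exc

    path = directory / FILE_NAMES["prescriptions"]
    reader = _sniff_reader(path)
    _require_columns(reader, "prescriptions", path)
    for i, row in enumerate(reader, start=2):
        bundle.prescriptions.append(
            PrescriptionRecord(
                person_id=row["person_id"],
                atc_code=row["atc_code"],
                dispense_date=_parse_date(row["dispense_date"], f"{path}:{i}"),
                prescriber_id=row["prescriber_id"],
            )
        )

    path = directory / FILE_NAMES["procedures"]
    reader = _sniff_reader(path)
    _require_columns(reader, "procedures", path)
    for i, row in enumerate(reader, start=2):
        bundle.procedures.append(
            ProcedureRecord(
                person_id=row["person_id"],
                ops_code=row["ops_code"],
                service_date=_parse_date(row["service_date"], f"{path}:{i}"),
            )
        )

    path = directory / FILE_NAMES["lab_services"]
    reader = _sniff_reader(path)
    _require_columns(reader, "lab_services", path)
    for i, row in enumerate(reader, start=2):
        bundle.lab_services.append(
            LabServiceRecord(
                person_id=row["person_id"],
                ebm_code=row["ebm_code"],
                service_date=_parse_date(row["service_date"], f"{path}:{i}"),
                physician_id=row["physician_id"],
            )
        )

    log.info(
        "read claims from %s: %d persons, %d diagnoses, %d prescriptions, "
        "%d procedures, %d lab services",
        directory, len(bundle.persons), len(bundle.diagnoses),
        len(bundle.prescriptions), len(bundle.procedures), len(bundle.lab_services),
    )
    return bundle


def _records_frame(records: Iterable, cols: list[str]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {}
        for f in fields(r):
            v = getattr(r, f.name)
            if isinstance(v, Enum):
                v = v.value
            d[f.name] = "" if v is None else v
        rows.append(d)
    return pd.DataFrame(rows, columns=cols)


def write_claims(bundle: ClaimsBundle, directory: str | Path, sep: str = ",") -> None:
    """Write a bundle as the five delimited tables (ISO dates, header row)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    streams = {
        "persons": bundle.persons,
        "diagnoses": bundle.diagnoses,
        "prescriptions": bundle.prescriptions,
        "procedures": bundle.procedures,
        "lab_services": bundle.lab_services,
    }
    for table, records in streams.items():
        frame = _records_frame(records, _COLUMNS[table])
        frame.to_csv(directory / FILE_NAMES[table], sep=sep, index=False)
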