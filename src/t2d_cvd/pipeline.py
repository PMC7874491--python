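"""End-to-end orchestration: simulate -> cohort -> classify -> report.

A run is driven by one :class:`RunConfig` (YAML-serializable).  Outputs are
a cohort table, four report tables mirroring the usual presentation of a
claims-based prevalence study, and a manifest that lets the run be
reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

from .claims_model import ClaimsBundle, Setting, Qualifier, read_claims, write_claims
from .cohort import AGE_BANDS, DURATION_CATEGORIES, build_cohort
from .cvd import (
    DEFINITION_NAMES,
    CodeSet,
    ObservationWindow,
    build_definition,
    match,
)
from .stats import PrevalenceEstimate, extrapolate, prevalence, stratify, window_sweep
from .synthetic_claims import SimulationConfig, generate

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "database_condition_prevalence", "selection_flow", "characteristics_table", "case_validation"]

#: number of SHI-insured persons in Germany in 2015, the extrapolation target
GERMAN_SHI_POPULATION_2015 = 70_728_398

#: one-year database prevalence conditions (ICD component sets)
DATABASE_CONDITIONS: dict[str, CodeSet] = {
    "essential_hypertension": CodeSet("i10", "ICD", frozenset({"I10"})),
    "chronic_heart_failure": CodeSet("i50", "ICD", frozenset({"I50"})),
    "stroke": CodeSet("stroke", "ICD", frozenset({"I60", "I61", "I62", "I63", "I64"})),
    "peripheral_vascular_disease": CodeSet("pvd", "ICD", frozenset({"I739", "I702"})),
    "acute_myocardial_infarction": CodeSet("ami", "ICD", frozenset({"I21"})),
    "chronic_kidney_disease_stage5": CodeSet("ckd5", "ICD", frozenset({"N185"})),
}


class RunConfig(BaseModel):
    """One reproducible analysis run.

    Exactly one input source: a directory of claims tables, or a simulation
    block.  Everything the analysis treats as a parameter — definitions,
    windows, the critical value, the reference population, the OPS toggle —
    is configurable here.
    """

    claims_dir: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    output_dir: str = "t2d_cvd_run"
    index_year: int = 2015
    lookback_start_year: int = 2010
    definitions: tuple[str, ...] = DEFINITION_NAMES
    use_ops: bool = True
    z: float = 1.96
    reference_population: int = GERMAN_SHI_POPULATION_2015
    write_claims_copy: bool = True

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.claims_dir is None) == (self.simulation is None):
            raise ValueError(
                "config must provide exactly one of claims_dir or a simulation block"
            )
        return self


def database_condition_prevalence(
    bundle: ClaimsBundle, year: int, z: float = 1.96
) -> pd.DataFrame:
    """One-year prevalence of common cardiovascular conditions, whole database.

    A person counts for a condition with at least one evidential diagnosis
    (confirmed ambulatory or any hospital setting) in the year; the
    denominator is every insured person.
    """
    carriers: dict[str, set[str]] = {name: set() for name in DATABASE_CONDITIONS}
    for d in bundle.diagnoses:
        if d.service_date.year != year:
            continue
        if d.setting is Setting.ambulatory and d.qualifier is not Qualifier.G:
            continue
        for name, cs in DATABASE_CONDITIONS.items():
            if match(d.icd_code, cs):
                carriers[name].add(d.person_id)
    denom = len(bundle.persons)
    rows = []
    for name, persons in carriers.items():
        est = prevalence(len(persons), denom, z=z) if denom else None
        rows.append(
            {
                "condition": name,
                "n_patients": len(persons),
                "denominator": denom,
                "percent": est.percent if est else float("nan"),
                "percent_1dp": est.percent_1dp if est else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def selection_flow(cohort: pd.DataFrame) -> pd.DataFrame:
    """Flow-of-selection tallies: database -> adults -> enrolled -> cases.

    Percentages are relative to the adult count, matching the convention of
    reporting the adult stratum as 100%.
    """
    n_total = len(cohort)
    adults = cohort[cohort["adult"]]
    n_adult = len(adults)
    enrolled = adults[adults["continuously_enrolled"]]
    n_enrolled = len(enrolled)
    cases = enrolled[enrolled["is_case"]]
    n_cases = len(cases)
    n_e14 = int(enrolled["excluded_e14_only"].sum())

    def pct(n: int, d: int) -> float:
        return prevalence(n, d).percent_1dp if d else float("nan")

    rows = [
        {"step": "persons_in_database", "n": n_total, "percent_of_adults": float("nan")},
        {"step": "adults_at_index", "n": n_adult, "percent_of_adults": 100.0},
        {"step": "continuously_enrolled", "n": n_enrolled, "percent_of_adults": pct(n_enrolled, n_adult)},
        {"step": "t2d_cases", "n": n_cases, "percent_of_adults": pct(n_cases, n_adult)},
        {"step": "excluded_e14_only", "n": n_e14, "percent_of_adults": pct(n_e14, n_adult)},
    ]
    return pd.DataFrame(rows)


def characteristics_table(cases: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics: strata shares and comorbidity/therapy flags."""
    n = len(cases)
    rows = []

    def add(parameter: str, count: int) -> None:
        est = prevalence(count, n) if n else None
        rows.append(
            {
                "parameter": parameter,
                "n": count,
                "percent": est.percent if est else float("nan"),
                "percent_1dp": est.percent_1dp if est else float("nan"),
            }
        )

    for sex in ("female", "male"):
        add(f"sex_{sex}", int((cases["sex"] == sex).sum()))
    for band in AGE_BANDS:
        add(f"age_{band}", int((cases["age_band"] == band).sum()))
    for cat in DURATION_CATEGORIES:
        add(f"duration_{cat}", int((cases["duration_category"] == cat).sum()))
    for flag in (
        "hypertension",
        "lipometabolic_disorder",
        "macrovascular_event",
        "microvascular_event",
        "t2d_hospitalization",
    ):
        if flag in cases.columns:
            add(flag, int(cases[flag].sum()))
    add("any_glucose_lowering_therapy", int((cases["therapy_class"] != "none").sum()))
    for label, grp in cases.groupby("therapy_class"):
        add(f"therapy_{label}", len(grp))
    return pd.DataFrame(rows)


def case_validation(cohort: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Sensitivity/specificity of the case algorithm against simulated truth.

    Computed among eligible persons only — the algorithm never sees the
    ineligible — and meaningful only on synthetic data.
    """
    merged = cohort.merge(truth, on="person_id", how="left")
    elig = merged[merged["eligible"]]
    tp = int((elig["is_case"] & elig["true_t2d"]).sum())
    fn = int((~elig["is_case"] & elig["true_t2d"]).sum())
    fp = int((elig["is_case"] & ~elig["true_t2d"]).sum())
    tn = int((~elig["is_case"] & ~elig["true_t2d"]).sum())
    return {
        "true_positive": tp,
        "false_negative": fn,
        "false_positive": fp,
        "true_negative": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline and return the output directory.

    Writes cohort.csv, table1-table4 CSVs, validation.json (simulated runs),
    extrapolation.json and manifest.json.  Deterministic for a fixed config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth: Optional[pd.DataFrame] = None
    if config.simulation is not None:
        log.info("simulating %d persons (seed %d)", config.simulation.n_persons, config.simulation.seed)
        bundle, truth = generate(config.simulation)
        if config.write_claims_copy:
            write_claims(bundle, out / "claims")
            truth.to_csv(out / "claims" / "ground_truth.csv", index=False)
    else:
        bundle = read_claims(config.claims_dir)

    windows = [
        ObservationWindow(y, config.index_year)
        for y in range(config.lookback_start_year, config.index_year + 1)
    ]
    cohort = build_cohort(
        bundle,
        index_year=config.index_year,
        windows=windows,
        definitions=config.definitions,
        use_ops=config.use_ops,
    )
    cohort.to_csv(out / "cohort.csv", index=False)

    flow = selection_flow(cohort)
    flow.to_csv(out / "selection_flow.csv", index=False)
    for _, r in flow.iterrows():
        log.info("selection: %-25s %d", r["step"], r["n"])

    table1 = database_condition_prevalence(bundle, config.index_year, z=config.z)
    table1.to_csv(out / "table1.csv", index=False)

    cases = cohort[cohort["is_case"]]
    table2 = characteristics_table(cases)
    table2.to_csv(out / "table2.csv", index=False)

    full_window = f"cvd_{config.definitions[0]}_{config.lookback_start_year}_{config.index_year}"
    table3 = stratify(cohort, by="sex", flag_column=full_window, z=config.z)
    table3.to_csv(out / "table3.csv", index=False)

    table4 = window_sweep(cohort, definitions=config.definitions, windows=windows, z=config.z)
    table4.to_csv(out / "table4.csv", index=False)

    n_cases = len(cases)
    n_cvd = int(cases[full_window].sum()) if n_cases else 0
    extra = extrapolate(n_cvd, max(len(cohort), 1), config.reference_population)
    (out / "extrapolation.json").write_text(
        json.dumps(
            {
                "cvd_cases_in_sample": extra.sample_numerator,
                "sample_size": extra.sample_denominator,
                "reference_population": extra.reference_population,
                "extrapolated_cvd_t2d_count": extra.extrapolated_count,
            },
            indent=2,
        )
    )

    if truth is not None:
        (out / "validation.json").write_text(json.dumps(case_validation(cohort, truth), indent=2))

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "row_counts": {
            "persons": len(bundle.persons),
            "diagnoses": len(bundle.diagnoses),
            "prescriptions": len(bundle.prescriptions),
            "procedures": len(bundle.procedures),
            "lab_services": len(bundle.lab_services),
        },
        "code_sets": {
            name: {
                "icd_include": sorted(
                    p for cs in build_definition(name).icd_sets for p in cs.include_prefixes
                ),
                "icd_exclude": sorted(
                    p for cs in build_definition(name).icd_sets for p in cs.exclude_prefixes
                ),
                "ops_include": sorted(
                    p for cs in build_definition(name).ops_sets for p in cs.include_prefixes
                ),
            }
            for name in config.definitions
        },
        "cohort_sha256": hashlib.sha256(
            cohort.to_csv(index=False).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)
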