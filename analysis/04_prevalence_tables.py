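#!/usr/bin/env python
"""Database-wide condition prevalences and cohort characteristics.

Writes results/table1.csv (one-year prevalence of common cardiovascular
conditions over the whole insured sample) and results/table2.csv (cohort
strata: sex, age bands, diabetes duration, comorbidity flags, therapy
classes).
"""

from pathlib import Path

import pandas as pd

from t2d_cvd.claims_model import read_claims
from t2d_cvd.pipeline import characteristics_table, database_condition_prevalence

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    claims_dir = ROOT / "scratch" / "claims"
    cohort_path = ROOT / "scratch" / "cohort.csv"
    if not (claims_dir.exists() and cohort_path.exists()):
        raise SystemExit("run analysis/01 and 02 first")

    bundle = read_claims(claims_dir)
    table1 = database_condition_prevalence(bundle, 2015)
    table1.to_csv(RESULTS / "table1.csv", index=False)
    print("one-year database prevalence, 2015:")
    for _, r in table1.iterrows():
        print(f"  {r['condition']:<32} {r['n_patients']:>6}  {r['percent_1dp']}%")

    cohort = pd.read_csv(cohort_path)
    cases = cohort[cohort["is_case"]]
    table2 = characteristics_table(cases)
    table2.to_csv(RESULTS / "table2.csv", index=False)
    print(f"\ncohort characteristics ({len(cases)} T2D cases); highlights:")
    for param in ("sex_female", "duration_5plus", "hypertension",
                  "any_glucose_lowering_therapy", "therapy_metformin_mono"):
        row = table2[table2["parameter"] == param]
        if not row.empty:
            print(f"  {param:<30} {row.iloc[0]['percent_1dp']}%")


if __name__ == "__main__":
    main()
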