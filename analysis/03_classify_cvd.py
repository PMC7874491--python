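#!/usr/bin/env python
"""Primary analysis: CVD prevalence among T2D cases, 2010-2015, narrow definition.

Sex-stratified prevalence with Wald intervals (the primary table of the
study design) and extrapolation of the CVD-in-T2D headcount to the 2015
German SHI population.  Writes results/table3.csv and
results/extrapolation.json.
"""

import json
from pathlib import Path

import pandas as pd

from t2d_cvd.pipeline import GERMAN_SHI_POPULATION_2015
from t2d_cvd.stats import extrapolate, stratify

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
PRIMARY = "cvd_narrow_2010_2015"


def main() -> None:
    cohort_path = ROOT / "scratch" / "cohort.csv"
    if not cohort_path.exists():
        raise SystemExit("run analysis/02_build_cohort.py first")
    cohort = pd.read_csv(cohort_path)

    table3 = stratify(cohort, by="sex", flag_column=PRIMARY)
    table3.to_csv(RESULTS / "table3.csv", index=False)
    print("CVD prevalence among T2D cases, narrow definition, 2010-2015:")
    for _, r in table3.iterrows():
        print(f"  {r['sex']:<7} {r['numerator']:>5}/{r['denominator']:<5} "
              f"{r['percent']:.2f}% ({r['ci_low']:.2f}; {r['ci_high']:.2f})  "
              f"mean age {r['mean_age']:.2f}")

    total = table3[table3["sex"] == "total"].iloc[0]
    extra = extrapolate(
        int(total["numerator"]), len(cohort), GERMAN_SHI_POPULATION_2015
    )
    (RESULTS / "extrapolation.json").write_text(
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
    print(f"extrapolated CVD-in-T2D count for {extra.reference_population:,} "
          f"insured: {extra.extrapolated_count:,}")


if __name__ == "__main__":
    main()
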