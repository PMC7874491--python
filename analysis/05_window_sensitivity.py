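#!/usr/bin/env python
"""Observation-window and definition sensitivity, with mechanism check.

Sweeps CVD prevalence over the six nested observation windows (2015 ...
2010-2015) and the three nested definitions, then compares the observed
fraction of truly CVD-positive cases visible in each window against the
closed form 1 - (1 - doc_prob)**years implied by independent per-year
documentation.  Writes results/table4.csv and results/window_mechanism.csv.
"""

import math
from pathlib import Path

import pandas as pd

from t2d_cvd.stats import window_sweep
from t2d_cvd.synthetic_claims import expected_observed_fraction

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DOC_PROB = 0.5  # must match the simulation config of analysis/01


def main() -> None:
    cohort_path = ROOT / "scratch" / "cohort.csv"
    claims_dir = ROOT / "scratch" / "claims"
    if not cohort_path.exists():
        raise SystemExit("run analysis/02_build_cohort.py first")
    cohort = pd.read_csv(cohort_path)
    truth = pd.read_csv(claims_dir / "ground_truth.csv")

    grid = window_sweep(cohort)
    grid.to_csv(RESULTS / "table4.csv", index=False)
    print("CVD prevalence (%) by window and definition:")
    print(grid.pivot(index="window", columns="definition", values="percent"))

    merged = cohort.merge(truth, on="person_id")
    cvd_cases = merged[merged["is_case"] & merged["true_cvd"]]
    rows = []
    for y in range(1, 7):
        observed = cvd_cases[f"cvd_wide_{2016 - y}_2015"].mean()
        expected = expected_observed_fraction(DOC_PROB, y)
        se = math.sqrt(expected * (1 - expected) / len(cvd_cases))
        rows.append({"window_years": y, "observed_fraction": round(observed, 4),
                     "expected_fraction": round(expected, 4),
                     "z_score": round((observed - expected) / se, 2)})
    mech = pd.DataFrame(rows)
    mech.to_csv(RESULTS / "window_mechanism.csv", index=False)
    print(f"\nvisibility of true CVD among {len(cvd_cases)} cases vs 1-(1-p)^y:")
    print(mech.to_string(index=False))
    print("\na one-year window sees only half the truly ill; six years see nearly all —"
          "\nthe reason short observation periods understate chronic-disease prevalence.")


if __name__ == "__main__":
    main()
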