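#!/usr/bin/env python
"""Generate the synthetic study population.

Simulates 20,000 insured persons (2010-2015) with latent T2D and CVD states,
per-year documentation probability 0.5, enrollment churn and deaths, and
writes the five claims tables plus ground truth under scratch/claims/.
A small row-count summary goes to results/simulation_summary.json.
"""

import json
from pathlib import Path

from t2d_cvd.claims_model import write_claims
from t2d_cvd.synthetic_claims import SimulationConfig, generate

ROOT = Path(__file__).resolve().parents[1]
CLAIMS_DIR = ROOT / "scratch" / "claims"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = SimulationConfig(n_persons=20_000, seed=1, doc_prob=0.5)
    bundle, truth = generate(cfg)
    write_claims(bundle, CLAIMS_DIR)
    truth.to_csv(CLAIMS_DIR / "ground_truth.csv", index=False)

    summary = {
        "config": json.loads(cfg.model_dump_json()),
        "persons": len(bundle.persons),
        "diagnoses": len(bundle.diagnoses),
        "prescriptions": len(bundle.prescriptions),
        "procedures": len(bundle.procedures),
        "lab_services": len(bundle.lab_services),
        "true_t2d": int(truth["true_t2d"].sum()),
        "true_cvd": int(truth["true_cvd"].sum()),
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "simulation_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {summary['persons']} persons to {CLAIMS_DIR}")
    print(f"  true T2D: {summary['true_t2d']}  true CVD: {summary['true_cvd']}")
    print(f"  claim rows: {summary['diagnoses']} dx, {summary['prescriptions']} rx, "
          f"{summary['procedures']} ops, {summary['lab_services']} lab")


if __name__ == "__main__":
    main()
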