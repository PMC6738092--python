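#!/usr/bin/env python
"""Simulate the three-cohort study (two discovery subgroups + validation).

Writes the cohorts in the package's TSV dialects under scratch/cohorts/ (large,
regenerable) and a per-cohort summary under results/.  Downstream analysis
scripts (02-06) read from scratch/cohorts/.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from lvisig import SimulationConfig, simulate_study, write_clinical, write_expression


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    outdir = ROOT / "scratch" / "cohorts"
    outdir.mkdir(parents=True, exist_ok=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    config = SimulationConfig(seed=args.seed)
    study = simulate_study(config)

    rows = []
    for name, cohort in study.cohorts.items():
        write_expression(cohort.expression, outdir / f"{name}_expression.tsv")
        write_clinical(cohort.clinical, outdir / f"{name}_clinical.tsv")
        truth = pd.DataFrame({"sample_id": cohort.truth.subtype.index,
                              "subtype": cohort.truth.subtype.to_numpy()})
        truth.to_csv(outdir / f"{name}_truth.tsv", sep="\t", index=False)
        lvi = cohort.clinical.data["lvi_status"] == "positive"
        rows.append({"cohort": name, "n_samples": len(cohort.clinical.data),
                     "n_genes": cohort.expression.shape[0],
                     "lvi_positive": int(lvi.sum()),
                     "lvi_prevalence_pct": round(100 * lvi.mean(), 1)})
    pd.DataFrame({"gene": study.up_genes + study.down_genes,
                  "direction": ["up"] * len(study.up_genes)
                  + ["down"] * len(study.down_genes)}
                 ).to_csv(outdir / "planted_genes.tsv", sep="\t", index=False)

    summary = pd.DataFrame(rows)
    summary.to_csv(results / "01_cohort_summary.tsv", sep="\t", index=False)
    print(f"seed {args.seed}: simulated {len(study.cohorts)} cohorts, "
          f"{config.n_genes} genes, {config.n_up}+{config.n_down} planted "
          f"(delta = {config.effect_size} log2 units)")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
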