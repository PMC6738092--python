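#!/usr/bin/env python
"""Clinicopathological association of the genomic subtypes in the validation cohort.

Cross-tabulates the assigned subtype against LVI status, tumour size, nodal
status, grade, ER/PR/HER2 and molecular subtype (counts with column
percentages, Pearson chi-squared) and writes the long-format report to
results/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from lvisig import read_clinical
from lvisig.association import association_report

COHORTS = ROOT / "scratch" / "cohorts"
FACTORS = ["lvi_status", "tumour_size", "nodal_status", "grade", "er", "pr",
           "her2", "molecular_subtype"]


def main() -> None:
    clin = read_clinical(COHORTS / "validation_clinical.tsv")
    labels = pd.read_csv(ROOT / "results" / "03_subtype_assignments.tsv",
                         sep="\t", index_col="sample_id")["subtype"]
    report = association_report(clin, labels, FACTORS)
    report.to_csv(ROOT / "results" / "05_association.tsv", sep="\t", index=False)
    print(report.to_string(index=False))
    significant = report.groupby("factor")["p"].first()
    print("\nfactors with chi-squared p < 0.0001:",
          ", ".join(sorted(significant[significant < 1e-4].index)))


if __name__ == "__main__":
    main()
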