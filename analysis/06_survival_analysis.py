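#!/usr/bin/env python
"""10-year overall survival of the genomic subtypes in the validation cohort.

Kaplan-Meier curves per subtype with the log-rank test, then univariate and
multivariate Cox proportional-hazards models over the standard covariate set.
Writes the KM curves and Cox tables to results/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from lvisig import read_clinical
from lvisig.survival import (build_survival_records, cap_followup, cox_fit,
                             cox_table, km_curve_table, km_estimate, logrank_test)

COHORTS = ROOT / "scratch" / "cohorts"


def main() -> None:
    clin = read_clinical(COHORTS / "validation_clinical.tsv")
    labels = pd.read_csv(ROOT / "results" / "03_subtype_assignments.tsv",
                         sep="\t", index_col="sample_id")["subtype"]
    records = cap_followup(build_survival_records(clin, labels))
    groups = labels.map({1: "subtype1", 2: "subtype2"})

    curves = km_estimate(records, groups)
    km_curve_table(curves).to_csv(ROOT / "results" / "06_km_curves.tsv",
                                  sep="\t", index=False)
    stat, p = logrank_test(records, groups)
    for name, curve in curves.items():
        print(f"{name}: n = {curve.n}, events = {curve.events}, "
              f"S(120 months) = {curve.survival_at(120.0):.3f}")
    print(f"log-rank chi2 = {stat:.2f}, p = {p:.3g}")

    uni = cox_table(cox_fit(records, mode="univariate"))
    multi = cox_table(cox_fit(records, mode="multivariate"))
    uni.to_csv(ROOT / "results" / "06_cox_univariate.tsv", sep="\t", index=False)
    multi.to_csv(ROOT / "results" / "06_cox_multivariate.tsv", sep="\t", index=False)
    sub = uni[uni["covariate"] == "subtype2"].iloc[0]
    print(f"univariate subtype-2 HR = {sub['HR']:.2f} "
          f"(95% CI {sub['ci_low']:.2f}-{sub['ci_high']:.2f}, p = {sub['p']:.3g}); "
          f"generator plants HR 1.78")
    print("\nmultivariate model:")
    print(multi.round(3).to_string(index=False))
    print("\nnote: in this generator the latent subtype IS the LVI expression "
          "state, so when clustering is near-perfect the lvi_positive and "
          "subtype2 indicators are almost collinear and the joint model splits "
          "their shared effect arbitrarily between them; the univariate "
          "subtype-2 HR is the estimate of the planted effect")


if __name__ == "__main__":
    main()
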