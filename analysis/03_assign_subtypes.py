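#!/usr/bin/env python
"""Cluster the validation cohort on the discovered signature into subtypes 1/2.

Hierarchical clustering (gene-wise z-score, 1 - Pearson distance, average
linkage, cut at k = 2); the higher-scoring cluster is the adverse subtype 2.
Reports agreement with the latent simulated subtype and writes the per-sample
assignments to results/ and the sample dendrogram to scratch/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from lvisig import read_clinical, read_expression, read_signature
from lvisig.clustering import assign_subtypes, linkage_to_newick

COHORTS = ROOT / "scratch" / "cohorts"


def main() -> None:
    from sklearn.metrics import adjusted_rand_score

    signature = read_signature(ROOT / "results" / "02_signature.tsv")
    expr = read_expression(COHORTS / "validation_expression.tsv")
    clin = read_clinical(COHORTS / "validation_clinical.tsv")
    truth = pd.read_csv(COHORTS / "validation_truth.tsv", sep="\t",
                        index_col="sample_id")["subtype"]

    assignment = assign_subtypes(expr, signature)
    out = pd.DataFrame({"sample_id": assignment.labels.index,
                        "subtype": assignment.labels.to_numpy(),
                        "score": assignment.scores.reindex(
                            assignment.labels.index).round(4).to_numpy()})
    out.to_csv(ROOT / "results" / "03_subtype_assignments.tsv", sep="\t", index=False)
    (ROOT / "scratch" / "validation_dendrogram.nwk").write_text(
        linkage_to_newick(assignment.sample_linkage, assignment.sample_ids) + "\n")

    ari = adjusted_rand_score(truth.loc[assignment.labels.index],
                              assignment.labels.to_numpy())
    agree = (assignment.labels == truth.loc[assignment.labels.index]).mean()
    lvi = clin.data["lvi_status"] == "positive"
    n2 = int((assignment.labels == 2).sum())
    print(f"subtype 2: {n2}/{len(assignment.labels)} samples "
          f"({100 * n2 / len(assignment.labels):.0f}%)")
    print(f"adjusted Rand index vs latent subtype: {ari:.3f}; "
          f"label agreement {100 * agree:.1f}%")
    print(f"LVI+ prevalence: subtype 2 "
          f"{100 * lvi[assignment.labels == 2].mean():.1f}% vs subtype 1 "
          f"{100 * lvi[assignment.labels == 1].mean():.1f}%")


if __name__ == "__main__":
    main()
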