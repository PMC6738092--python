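#!/usr/bin/env python
"""Over-representation analysis of the discovered signature.

Builds a synthetic gene-set database over the simulated universe (the planted
up and down sets, their union, and size-matched random sets), runs the
hypergeometric ORA with BH-FDR, and writes the enrichment table to results/.
The planted sets should dominate; random sets should stay near adj_p ~ 1.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from lvisig import read_expression, read_signature
from lvisig.enrichment import enrichment_table, ora
from lvisig.io import GeneSetDatabase

COHORTS = ROOT / "scratch" / "cohorts"
ALPHA = 0.01


def main() -> None:
    signature = read_signature(ROOT / "results" / "02_signature.tsv")
    universe = read_expression(COHORTS / "validation_expression.tsv").gene_ids
    planted = pd.read_csv(COHORTS / "planted_genes.tsv", sep="\t")
    up = planted.loc[planted["direction"] == "up", "gene"].tolist()
    down = planted.loc[planted["direction"] == "down", "gene"].tolist()

    rng = np.random.default_rng(0)
    sets = {"PLANTED:up": ("planted up-regulated genes", up),
            "PLANTED:down": ("planted down-regulated genes", down),
            "PLANTED:all": ("all planted genes", up + down)}
    for i in range(5):
        members = list(rng.choice(universe, size=60, replace=False))
        sets[f"RANDOM:{i}"] = (f"random 60-gene set {i}", members)

    rows = ora(signature.genes, GeneSetDatabase(sets), universe)
    table = enrichment_table(rows)
    table.drop(columns=["members"]).to_csv(ROOT / "results" / "04_enrichment.tsv",
                                           sep="\t", index=False)
    significant = table[table["adj_p"] < ALPHA]
    print(table.drop(columns=["members"]).to_string(index=False))
    print(f"\n{len(significant)} of {len(table)} sets significant at "
          f"adj_p < {ALPHA}: {', '.join(significant['ontology_id'])}")


if __name__ == "__main__":
    main()
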