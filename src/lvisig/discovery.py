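"""Cross-subgroup signature discovery: top-K WAD lists and their sign-consistent overlap."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import BoundsError
from .io import GeneSignature
from .wad import rank_genes

logger = logging.getLogger(__name__)

DEFAULT_K = 350


@dataclass
class RankedList:
    """Top-K genes of one discovery subgroup, with their signed WAD values."""

    cohort_name: str
    genes: list[str]
    wad: dict[str, float] = field(default_factory=dict)
    k: int = 0

    def __len__(self) -> int:
        return len(self.genes)


def top_k(wad_table: pd.DataFrame, k: int, cohort_name: str = "",
          direction: str = "both") -> RankedList:
    """First ``k`` genes under the WAD ranking contract, with signs attached."""
    n_genes = len(wad_table)
    if k < 1 or k > n_genes:
        raise BoundsError(f"K must satisfy 1 <= K <= {n_genes}, got {k}")
    ordered = rank_genes(wad_table, direction=direction)[:k]
    wad = {g: float(wad_table.loc[g, "wad"]) for g in ordered}
    return RankedList(cohort_name=cohort_name, genes=ordered, wad=wad, k=k)


def intersect_signatures(list_a: RankedList, list_b: RankedList) -> GeneSignature:
    """Sign-consistent overlap of two ranked lists.

    Genes present in both lists with positive WAD in both become the up list;
    negative in both, the down list.  Discordant-sign overlaps are excluded and
    logged.  Output is ordered by the mean of the two within-list ranks
    (1-based positions), ties broken lexicographically, so the result is
    symmetric in its arguments up to that deterministic order.
    """
    rank_a = {g: i + 1 for i, g in enumerate(list_a.genes)}
    rank_b = {g: i + 1 for i, g in enumerate(list_b.genes)}
    common = set(rank_a) & set(rank_b)
    up, down, discordant = [], [], []
    for gene in common:
        wa, wb = list_a.wad[gene], list_b.wad[gene]
        if wa > 0 and wb > 0:
            up.append(gene)
        elif wa < 0 and wb < 0:
            down.append(gene)
        else:
            discordant.append(gene)
    if discordant:
        logger.info("intersect_signatures: %d overlapping genes had discordant signs: %s",
                    len(discordant), sorted(discordant)[:10])

    def mean_rank(gene: str) -> float:
        return (rank_a[gene] + rank_b[gene]) / 2.0

    up.sort(key=lambda g: (mean_rank(g), g))
    down.sort(key=lambda g: (mean_rank(g), g))
    provenance = {
        "cohorts": [list_a.cohort_name, list_b.cohort_name],
        "k": [list_a.k, list_b.k],
        "discordant_excluded": sorted(discordant),
    }
    return GeneSignature(up=up, down=down, provenance=provenance)


def discover_signature(wad_a: pd.DataFrame, wad_b: pd.DataFrame, k: int = DEFAULT_K,
                       per_direction: bool = False,
                       names: tuple[str, str] = ("discovery-A", "discovery-B")) -> GeneSignature:
    """Derive the overlap signature from two per-subgroup WAD tables.

    With ``per_direction=True`` each subgroup contributes a top-K up list and a
    top-K down list instead of a single top-K by \\|WAD\\|.
    """
    if not per_direction:
        return intersect_signatures(top_k(wad_a, k, names[0]), top_k(wad_b, k, names[1]))
    sig_up = intersect_signatures(top_k(wad_a, k, names[0], "up"),
                                  top_k(wad_b, k, names[1], "up"))
    sig_down = intersect_signatures(top_k(wad_a, k, names[0], "down"),
                                    top_k(wad_b, k, names[1], "down"))
    provenance = {"cohorts": list(names), "k": [k, k], "per_direction": True}
    return GeneSignature(up=sig_up.up, down=sig_down.down, provenance=provenance)
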