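"""Over-representation analysis (ORA) with Benjamini-Hochberg FDR control.

For a query signature of q genes inside a universe of N genes and a gene set
with m members in the universe, the observed overlap O is tested against the
hypergeometric upper tail P[X >= O]; the expected overlap is E = q * m / N and
the enrichment ratio R = O / E.  Only over-representation is tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InputError
from .io import GeneSetDatabase

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


@dataclass
class EnrichmentRow:
    ontology_id: str
    name: str
    m: int               # set members within the universe
    observed: int        # signature genes within the set
    expected: float      # q * m / N
    ratio: float         # observed / expected
    p: float             # hypergeometric upper tail
    adj_p: float         # BH-adjusted
    members: tuple[str, ...]  # the observed signature genes, sorted


def enrichment_ratio(observed: int, expected: float) -> float:
    """O / E with the O = 0 convention R = 0."""
    if expected <= 0:
        raise DomainError("expected overlap must be positive")
    return observed / expected


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(signature_genes, database: GeneSetDatabase, universe,
        alpha: float | None = None) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``signature_genes`` in each gene set.

    Genes outside the universe are dropped (and logged); one row is produced
    per set with at least one universe member; rows are sorted by adjusted p
    (ties by ontology id).  If ``alpha`` is given, only rows with
    adj_p < alpha are returned.
    """
    universe_set = set(universe)
    if not universe_set:
        raise InputError("empty gene universe")
    n_universe = len(universe_set)
    query = set(signature_genes) & universe_set
    dropped = len(set(signature_genes)) - len(query)
    if dropped:
        logger.info("ora: dropped %d signature genes outside the universe", dropped)
    if not query:
        logger.warning("ora: signature empty after intersection with universe")
        return []
    q = len(query)

    rows: list[EnrichmentRow] = []
    for set_id, (name, members) in database.sets.items():
        in_universe = set(members) & universe_set
        m = len(in_universe)
        if m == 0:
            continue
        overlap = sorted(query & in_universe)
        observed = len(overlap)
        expected = q * m / n_universe
        p = float(hypergeom.sf(observed - 1, n_universe, m, q))
        rows.append(EnrichmentRow(
            ontology_id=set_id, name=name, m=m, observed=observed,
            expected=expected, ratio=observed / expected,
            p=min(p, 1.0), adj_p=np.nan, members=tuple(overlap)))
    if not rows:
        return rows
    adj = bh_adjust([max(r.p, np.nextafter(0, 1)) for r in rows])
    for row, a in zip(rows, adj):
        row.adj_p = float(a)
    rows.sort(key=lambda r: (r.adj_p, r.ontology_id))
    if alpha is not None:
        rows = [r for r in rows if r.adj_p < alpha]
    return rows


def enrichment_table(rows: list[EnrichmentRow]):
    """Result rows as a DataFrame (expected/ratio rounded to 2 dp for display)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "ontology_id": [r.ontology_id for r in rows],
            "name": [r.name for r in rows],
            "genes_in_ontology": [r.m for r in rows],
            "observed": [r.observed for r in rows],
            "expected": [round(r.expected, 2) for r in rows],
            "enrichment": [round(r.ratio, 2) for r in rows],
            "p": [r.p for r in rows],
            "adj_p": [r.adj_p for r in rows],
            "members": [";".join(r.members) for r in rows],
        }
    )
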