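"""Weighted average difference (WAD) ranking of differential expression.

For gene *g* with log2 group means x+ (LVI-positive) and x- (LVI-negative):

    AD_g  = x+_g - x-_g                                  (average difference)
    w_g   = (xbar_g - min_h xbar_h) / (max_h xbar_h - min_h xbar_h)
    WAD_g = AD_g * w_g

where xbar_g is the overall mean over all samples, so the weight is the min-max
normalised expression level across genes.  WAD favours genes that are both
shifted between groups and well expressed; no variance moderation is applied
and no p-value is assigned.  SEM columns are reported for completeness but play
no role in the ranking.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DomainError, GroupSizeError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

WAD_COLUMNS = ["mean_pos", "sem_pos", "mean_neg", "sem_neg", "mean_all",
               "ad", "weight", "wad", "rank"]


def compute_wad(matrix: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-gene WAD table for a two-group comparison.

    ``labels`` maps every sample of ``matrix`` to "positive" or "negative"
    ("unknown" samples must be removed by the caller).  Returns a DataFrame
    indexed by gene with columns mean_pos, sem_pos, mean_neg, sem_neg,
    mean_all, ad, weight, wad and rank (1 = largest \\|WAD\\|).
    """
    labels = labels.astype(str)
    sample_set = set(matrix.sample_ids)
    if set(labels.index) < sample_set or not sample_set <= set(labels.index):
        missing = sample_set - set(labels.index)
        if missing:
            raise DomainError(f"labels missing for samples: {sorted(missing)[:5]}")
    labels = labels.loc[matrix.sample_ids]
    bad = set(labels.unique()) - {"positive", "negative"}
    if bad:
        raise DomainError(f"labels must be positive/negative, got extra levels {sorted(bad)}")

    values = matrix.values.to_numpy(dtype=float)
    pos_mask = (labels == "positive").to_numpy()
    neg_mask = ~pos_mask
    n_pos, n_neg = int(pos_mask.sum()), int(neg_mask.sum())
    if n_pos < 2 or n_neg < 2:
        raise GroupSizeError(
            f"each group needs >= 2 samples (positive={n_pos}, negative={n_neg})")

    pos = values[:, pos_mask]
    neg = values[:, neg_mask]
    mean_pos = pos.mean(axis=1)
    mean_neg = neg.mean(axis=1)
    sem_pos = pos.std(axis=1, ddof=1) / np.sqrt(n_pos)
    sem_neg = neg.std(axis=1, ddof=1) / np.sqrt(n_neg)
    mean_all = values.mean(axis=1)
    ad = mean_pos - mean_neg

    lo, hi = mean_all.min(), mean_all.max()
    if hi > lo:
        weight = (mean_all - lo) / (hi - lo)
    else:
        # all genes share one overall mean; weights carry no information
        logger.warning("degenerate WAD weights: all overall means identical; using w = 1")
        weight = np.ones_like(mean_all)
    wad = ad * weight

    table = pd.DataFrame(
        {
            "mean_pos": mean_pos, "sem_pos": sem_pos,
            "mean_neg": mean_neg, "sem_neg": sem_neg,
            "mean_all": mean_all, "ad": ad, "weight": weight, "wad": wad,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    order = _sorted_index(table, "both")
    table["rank"] = pd.Series(np.arange(1, len(table) + 1), index=order).loc[table.index]
    return table


def _sorted_index(table: pd.DataFrame, direction: str) -> pd.Index:
    if direction == "both":
        key = -table["wad"].abs()
    elif direction == "up":
        key = -table["wad"]
    elif direction == "down":
        key = table["wad"]
    else:
        raise DomainError(f"direction must be both/up/down, got {direction!r}")
    tmp = pd.DataFrame({"key": np.asarray(key), "symbol": table.index.astype(str)})
    tmp = tmp.sort_values(["key", "symbol"], kind="mergesort")
    return pd.Index(tmp["symbol"].to_numpy(), name="gene")


def rank_genes(wad_table: pd.DataFrame, direction: str = "both") -> list[str]:
    """Genes ordered by the WAD ranking contract.

    direction="both" sorts by \\|WAD\\| descending, "up" by signed WAD descending,
    "down" by signed WAD ascending; ties break lexicographically on the symbol.
    """
    return list(_sorted_index(wad_table, direction))


def write_wad_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "gene"
    out = out.rename(columns={"ad": "AD", "wad": "WAD"})
    out.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")
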