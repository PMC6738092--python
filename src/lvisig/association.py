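"""Contingency tables, percentages and chi-squared tests for clinicopathological factors.

Reproduces the subtype-association reporting layout: counts with column
percentages (half-up rounding, 1 dp), Pearson chi-squared without continuity
correction, listwise exclusion of "unknown" per factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import DegenerateTableError, DomainError, EmptyCohortError, StructuralZeroError
from .io import ClinicalTable


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (printed-table convention, unlike banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """100 * count / total, rounded half-up; ndigits=0 gives whole percent."""
    if total <= 0:
        raise EmptyCohortError("percentage of an empty denominator")
    return round_half_up(100.0 * count / total, ndigits)


@dataclass
class ContingencyTable:
    row_factor: str
    col_factor: str
    counts: pd.DataFrame          # integer counts, rows x columns
    column_percent: pd.DataFrame  # per-column percentages, 1 dp
    statistic: float
    dof: int
    p: float


def chi2_test(counts: pd.DataFrame | np.ndarray, yates: bool = False):
    """Pearson chi-squared on a counts table -> (statistic, dof, p).

    Continuity correction is off by default; ``yates=True`` enables it for
    2x2 tables.  An expected count of zero (an empty row or column margin)
    raises StructuralZeroError.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DegenerateTableError("chi-squared needs a table with >= 2 rows and columns")
    if (arr < 0).any():
        raise DomainError("negative cell count")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected == 0).any():
        raise StructuralZeroError("expected cell count of zero (empty margin)")
    stat, p, dof, _ = chi2_contingency(arr, correction=yates)
    return float(stat), int(dof), float(p)


def crosstab(clinical: ClinicalTable | pd.DataFrame, row_factor: str,
             col_factor: str, yates: bool = False) -> ContingencyTable:
    """Counts, column percentages and chi-squared for two categorical factors.

    Samples with "unknown" (or missing) in either factor are excluded
    listwise for this table only.
    """
    df = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    for factor in (row_factor, col_factor):
        if factor not in df.columns:
            raise DomainError(f"factor {factor!r} not present")
    sub = df[[row_factor, col_factor]].astype(str)
    mask = ~(sub.isin(["unknown", "nan", "None"]).any(axis=1) | sub.isna().any(axis=1))
    sub = sub[mask]
    counts = pd.crosstab(sub[row_factor], sub[col_factor])
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DegenerateTableError(
            f"factor pair ({row_factor}, {col_factor}) has fewer than 2 observed levels")
    stat, dof, p = chi2_test(counts, yates=yates)
    col_totals = counts.sum(axis=0)
    pct = counts.copy().astype(float)
    for col in counts.columns:
        pct[col] = [percentage(c, int(col_totals[col]), 1) for c in counts[col]]
    return ContingencyTable(row_factor=row_factor, col_factor=col_factor,
                            counts=counts, column_percent=pct,
                            statistic=stat, dof=dof, p=p)


def prevalence(clinical: ClinicalTable | pd.DataFrame, factor: str, level: str,
               ndigits: int = 1) -> tuple[int, int, float]:
    """(count, total, percent) of ``level`` among non-unknown values of ``factor``."""
    df = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    if factor not in df.columns:
        raise DomainError(f"factor {factor!r} not present")
    observed = df[factor][df[factor].astype(str) != "unknown"].dropna()
    total = len(observed)
    if total == 0:
        raise EmptyCohortError(f"no observed values for factor {factor!r}")
    count = int((observed.astype(str) == level).sum())
    return count, total, percentage(count, total, ndigits)


def association_report(clinical: ClinicalTable | pd.DataFrame, labels: pd.Series,
                       factors: list[str]) -> pd.DataFrame:
    """Long-format subtype-association table: one row per factor level.

    ``labels`` holds the per-sample genomic subtype (1/2).  Columns carry
    counts with column percentages for each subtype, the level total and the
    per-factor chi-squared p-value.
    """
    df = (clinical.data if isinstance(clinical, ClinicalTable) else clinical).copy()
    df = df.loc[labels.index]
    df["genomic_subtype"] = labels.astype(int)
    out_rows = []
    for factor in factors:
        table = crosstab(df, factor, "genomic_subtype")
        for level in table.counts.index:
            row = {"factor": factor, "level": level}
            for col in table.counts.columns:
                row[f"subtype{col}"] = (
                    f"{table.counts.loc[level, col]} "
                    f"({table.column_percent.loc[level, col]:.1f}%)")
            row["total"] = int(table.counts.loc[level].sum())
            row["p"] = table.p
            out_rows.append(row)
    return pd.DataFrame(out_rows)
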