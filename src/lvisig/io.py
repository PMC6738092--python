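"""Containers and readers/writers for expression, clinical, signature and gene-set data.

All tabular formats are plain tab-separated text.  Expression matrices are genes x
samples on the log2 scale; clinical tables carry one row per sample with the
clinicopathological factors used throughout the pipeline (LVI status, tumour size,
nodal status, grade, ER/PR/HER2, molecular subtype) plus survival follow-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CohortError, DomainError, FormatError, SchemaError

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44

#: enumerated domains for the categorical clinical columns ("unknown" is always legal)
CATEGORICAL_DOMAINS: dict[str, frozenset[str]] = {
    "lvi_status": frozenset({"positive", "negative"}),
    "tumour_size": frozenset({"ge2cm", "lt2cm"}),
    "nodal_status": frozenset({"positive", "negative"}),
    "grade": frozenset({"grade3", "grade1-2"}),
    "er": frozenset({"positive", "negative"}),
    "pr": frozenset({"positive", "negative"}),
    "her2": frozenset({"positive", "negative"}),
    "molecular_subtype": frozenset(
        {"LuminalA", "LuminalB", "HER2-enriched", "Basal-like", "Normal-like"}
    ),
}

#: accepted aliases, e.g. the TCGA tumour-size dialect (T stage instead of cm cutoff)
_TOKEN_ALIASES: dict[str, dict[str, str]] = {
    "tumour_size": {"T2-4": "ge2cm", "T1": "lt2cm"},
    "grade": {"grade1,2": "grade1-2", "grade12": "grade1-2"},
}

_EVENT_ALIASES = {"death": "death", "censored": "censored", "1": "death", "0": "censored",
                  "dead": "death", "alive": "censored"}

CLINICAL_COLUMNS = [
    "sample_id", "lvi_status", "tumour_size", "nodal_status", "grade",
    "er", "pr", "her2", "molecular_subtype", "followup_time", "event",
]


@dataclass
class ExpressionMatrix:
    """Log2 expression, genes in rows and samples in columns."""

    values: pd.DataFrame
    platform_note: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DomainError(f"duplicate gene identifiers after collapse: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            raise DomainError("duplicate sample identifiers in expression matrix")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise DomainError("expression matrix contains NaN or infinite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.platform_note)

    def restrict_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids), :], self.platform_note)


@dataclass
class ClinicalTable:
    """Per-sample phenotype and follow-up; indexed by sample_id."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise DomainError("duplicate sample identifiers in clinical table")
        if (self.data["followup_time"] < 0).any():
            raise DomainError("negative follow-up time")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def restrict_samples(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())


@dataclass
class GeneSignature:
    """Ordered up- and down-regulated gene lists with discovery provenance."""

    up: list[str]
    down: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise DomainError("signature up and down lists overlap")
        if any(not g for g in self.up + self.down):
            raise DomainError("signature contains an empty gene symbol")

    @property
    def genes(self) -> list[str]:
        return list(self.up) + list(self.down)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class GeneSetDatabase:
    """Mapping from ontology/pathway identifier to (name, member genes)."""

    sets: dict[str, tuple[str, list[str]]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression


def collapse_duplicates(matrix: ExpressionMatrix | pd.DataFrame) -> ExpressionMatrix:
    """Collapse repeated gene rows to one row per symbol.

    The retained row is the duplicate with the highest overall mean (the usual
    probe-to-gene collapse convention); ties keep the earliest row.
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    note = matrix.platform_note if isinstance(matrix, ExpressionMatrix) else ""
    if not df.index.has_duplicates:
        return ExpressionMatrix(df.copy(), note)
    means = df.to_numpy().mean(axis=1)
    best: dict[str, int] = {}
    for i, gene in enumerate(df.index):
        if gene not in best or means[i] > means[best[gene]]:
            best[gene] = i
    keep = sorted(best.values())
    n_dropped = len(df) - len(keep)
    logger.info("collapse_duplicates: dropped %d duplicate gene rows", n_dropped)
    return ExpressionMatrix(df.iloc[keep].copy(), note)


def read_expression(path: str | Path, already_log2: bool = True,
                    platform_note: str = "") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene symbols, header sample IDs).

    Raw-scale input (``already_log2=False``) is transformed as log2(x + 1);
    duplicate gene symbols are collapsed to the max-mean row.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing expression file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"expression file has no data body: {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise FormatError(f"non-numeric expression value at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    if df.isna().to_numpy().any():
        raise FormatError(f"missing expression values in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if not already_log2:
        if (df.to_numpy() < 0).any():
            raise DomainError("negative expression value on raw scale; cannot log2-transform")
        df = np.log2(df + 1.0)
    out = collapse_duplicates(df)
    out.platform_note = platform_note
    return out


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# clinical


def _normalise_token(column: str, value: object) -> str:
    token = "" if pd.isna(value) else str(value).strip()
    token = _TOKEN_ALIASES.get(column, {}).get(token, token)
    if token in CATEGORICAL_DOMAINS[column] or token == "unknown":
        return token
    if token:
        logger.warning("clinical column %s: unknown token %r mapped to 'unknown'", column, token)
    return "unknown"


def read_clinical(path: str | Path, time_unit: str = "months") -> ClinicalTable:
    """Read a per-sample clinical TSV.

    ``time_unit`` may be "months" (default) or "days"; day-scale follow-up is
    converted to months by dividing by 30.44.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing clinical file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical file missing mandatory columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise DomainError("duplicate sample_id in clinical file")
    out = pd.DataFrame(index=pd.Index(df["sample_id"].astype(str), name="sample_id"))
    for col in CATEGORICAL_DOMAINS:
        out[col] = [_normalise_token(col, v) for v in df[col]]
    time = pd.to_numeric(df["followup_time"], errors="coerce")
    if time.isna().any():
        raise FormatError("non-numeric followup_time in clinical file")
    if time_unit == "days":
        time = time / DAYS_PER_MONTH
    elif time_unit != "months":
        raise DomainError(f"unsupported time unit {time_unit!r}")
    out["followup_time"] = time.to_numpy(dtype=float)
    events = []
    for v in df["event"]:
        token = str(v).strip().lower()
        if token not in _EVENT_ALIASES:
            raise DomainError(f"unrecognised event token {v!r} (expected death/censored)")
        events.append(_EVENT_ALIASES[token])
    out["event"] = events
    return ClinicalTable(out)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    df = table.data.reset_index()
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# signatures and gene sets


def read_signature(path: str | Path) -> GeneSignature:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing signature file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene", "direction") if c not in df.columns]
    if missing:
        raise SchemaError(f"signature file missing columns: {missing}")
    up, down = [], []
    for gene, direction in zip(df["gene"], df["direction"]):
        if direction == "up":
            up.append(gene)
        elif direction == "down":
            down.append(gene)
        else:
            raise DomainError(f"signature direction must be up/down, got {direction!r}")
    return GeneSignature(up=up, down=down)


def write_signature(signature: GeneSignature, path: str | Path) -> None:
    rows = [{"gene": g, "direction": "up"} for g in signature.up]
    rows += [{"gene": g, "direction": "down"} for g in signature.down]
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_gmt(path: str | Path) -> GeneSetDatabase:
    """Read a standard GMT file: set id, description, then member genes, tab-separated."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing GMT file: {path}")
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"malformed GMT line {lineno}: fewer than 3 fields")
            set_id, name, *members = fields
            if set_id in sets:
                raise FormatError(f"duplicate gene-set id {set_id!r} at GMT line {lineno}")
            unique_members = list(dict.fromkeys(m for m in members if m))
            sets[set_id] = (name, unique_members)
    return GeneSetDatabase(sets=sets, source=str(path))


def write_gmt(database: GeneSetDatabase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for set_id, (name, members) in database.sets.items():
            fh.write("\t".join([set_id, name, *members]) + "\n")


# ---------------------------------------------------------------------------
# cohort assembly


def align_cohort(matrix: ExpressionMatrix,
                 clinical: ClinicalTable) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both tables to their common samples, in expression-matrix order."""
    common = [s for s in matrix.sample_ids if s in set(clinical.sample_ids)]
    if not common:
        raise CohortError("expression and clinical tables share no samples")
    dropped_expr = len(matrix.sample_ids) - len(common)
    dropped_clin = len(clinical.sample_ids) - len(common)
    if dropped_expr or dropped_clin:
        logger.info("align_cohort: dropped %d expression and %d clinical samples",
                    dropped_expr, dropped_clin)
    return matrix.restrict_samples(common), clinical.restrict_samples(common)


# ---------------------------------------------------------------------------
# packaged reference data (transcribed from the original METABRIC/TCGA study tables)


def _data_path(name: str):
    return resources.files("lvisig.data").joinpath(name)


def load_reference_signature() -> GeneSignature:
    """The published 99-gene LVI signature (42 up-, 57 down-regulated genes)."""
    with resources.as_file(_data_path("lvi_signature_99.tsv")) as p:
        return read_signature(p)


def load_reference_enrichment() -> pd.DataFrame:
    """Published gene-ontology enrichment rows for the 99-gene signature.

    Columns: ontology_id, name, genes_in_ontology, expected (as printed, 2 dp),
    p_printed, members (semicolon-separated observed signature genes).
    """
    with resources.as_file(_data_path("published_enrichment.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_reference_subtype_counts() -> pd.DataFrame:
    """Published genomic-subtype x clinicopathology counts (METABRIC and TCGA blocks)."""
    with resources.as_file(_data_path("published_subtype_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_reference_prevalence() -> pd.DataFrame:
    """Published LVI-positive counts and cohort sizes."""
    with resources.as_file(_data_path("published_lvi_prevalence.tsv")) as p:
        return pd.read_csv(p, sep="\t")
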