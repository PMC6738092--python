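"""End-to-end orchestration: discovery -> subtyping -> enrichment -> association -> survival.

File-based runs are driven by a ``RunConfig`` (YAML), write every artifact
under an output directory and record a JSON manifest (config echo, package
version, seed, sha256 checksums of inputs and outputs) so a run can be
reproduced and diffed exactly.
"""

from __future__ import annotations

import contextlib
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import association_report
from .clustering import ClusteringParams, assign_subtypes
from .discovery import DEFAULT_K, discover_signature
from .enrichment import enrichment_table, ora
from .errors import LvisigError, ValidationError
from .io import (ClinicalTable, ExpressionMatrix, GeneSignature, align_cohort,
                 read_clinical, read_expression, read_gmt, write_signature)
from .survival import (build_survival_records, cap_followup, cox_fit, cox_table,
                       km_curve_table, km_estimate, logrank_test)
from .wad import compute_wad, write_wad_table

logger = logging.getLogger(__name__)


@contextlib.contextmanager
def _stage(name: str):
    """Attach the pipeline stage name to any lvisig error raised inside."""
    try:
        yield
    except LvisigError as exc:
        exc.args = (f"[stage {name}] {exc}",)
        raise


@dataclass
class RunConfig:
    """Paths and parameters for a full file-based run."""

    expression_a: str = ""
    clinical_a: str = ""
    expression_b: str = ""
    clinical_b: str = ""
    expression_validation: str = ""
    clinical_validation: str = ""
    signature: str = ""        # optional pre-computed signature (skips discovery)
    gmt: str = ""              # optional gene-set database for ORA
    k: int = DEFAULT_K
    per_direction: bool = False
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    alpha: float = 0.01
    factors: list[str] = field(default_factory=lambda: [
        "lvi_status", "tumour_size", "nodal_status", "grade", "er", "pr", "her2",
        "molecular_subtype"])
    covariates: list[str] = field(default_factory=list)
    seed: int = 0
    outdir: str = "lvisig-run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "clustering" in raw and isinstance(raw["clustering"], dict):
            raw["clustering"] = ClusteringParams(**raw["clustering"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        problems = []
        if self.k < 1:
            problems.append("K must be >= 1")
        if not 0 < self.alpha < 1:
            problems.append("alpha must lie in (0, 1)")
        for attr in ("expression_a", "clinical_a", "expression_b", "clinical_b",
                     "expression_validation", "clinical_validation", "signature", "gmt"):
            value = getattr(self, attr)
            if value and not Path(value).exists():
                problems.append(f"{attr} path does not exist: {value}")
        if problems:
            raise ValidationError("; ".join(problems))


@dataclass
class DiscoveryResult:
    wad_a: pd.DataFrame
    wad_b: pd.DataFrame
    signature: GeneSignature


@dataclass
class ValidationResult:
    assignment: object                 # SubtypeAssignment
    association: pd.DataFrame
    enrichment: pd.DataFrame | None
    km_table: pd.DataFrame
    logrank: tuple[float, float]
    cox_univariate: pd.DataFrame
    cox_multivariate: pd.DataFrame


def _lvi_labels(clinical: ClinicalTable) -> pd.Series:
    s = clinical.data["lvi_status"]
    return s[s.isin(["positive", "negative"])]


def run_discovery_frames(expr_a: ExpressionMatrix, clin_a: ClinicalTable,
                         expr_b: ExpressionMatrix, clin_b: ClinicalTable,
                         k: int = DEFAULT_K, per_direction: bool = False,
                         names: tuple[str, str] = ("discovery-A", "discovery-B"),
                         ) -> DiscoveryResult:
    """In-memory discovery: per-subgroup WAD tables and the overlap signature."""
    with _stage("discovery:align"):
        expr_a, clin_a = align_cohort(expr_a, clin_a)
        expr_b, clin_b = align_cohort(expr_b, clin_b)
    with _stage("discovery:wad"):
        labels_a = _lvi_labels(clin_a)
        labels_b = _lvi_labels(clin_b)
        wad_a = compute_wad(expr_a.restrict_samples(labels_a.index), labels_a)
        wad_b = compute_wad(expr_b.restrict_samples(labels_b.index), labels_b)
    with _stage("discovery:intersect"):
        signature = discover_signature(wad_a, wad_b, k=k, per_direction=per_direction,
                                       names=names)
    return DiscoveryResult(wad_a=wad_a, wad_b=wad_b, signature=signature)


def run_validation_frames(expr: ExpressionMatrix, clin: ClinicalTable,
                          signature: GeneSignature,
                          params: ClusteringParams | None = None,
                          factors: list[str] | None = None,
                          covariates: list[str] | None = None,
                          database=None, universe=None,
                          alpha: float | None = None) -> ValidationResult:
    """In-memory validation: subtype, associate, enrich, and survival-test a cohort."""
    factors = factors or ["lvi_status", "tumour_size", "nodal_status", "grade",
                          "er", "pr", "her2", "molecular_subtype"]
    with _stage("validation:align"):
        expr, clin = align_cohort(expr, clin)
    with _stage("validation:subtype"):
        assignment = assign_subtypes(expr, signature, params)
    with _stage("validation:associate"):
        usable = [f for f in factors if f in clin.data.columns]
        association = association_report(clin, assignment.labels, usable)
    enrichment = None
    if database is not None:
        with _stage("validation:enrich"):
            rows = ora(signature.genes, database,
                       universe if universe is not None else expr.gene_ids, alpha=None)
            enrichment = enrichment_table(rows)
            if alpha is not None:
                enrichment = enrichment[enrichment["adj_p"] < alpha].reset_index(drop=True)
    with _stage("validation:survival"):
        records = cap_followup(build_survival_records(clin, assignment.labels))
        groups = assignment.labels.map({1: "subtype1", 2: "subtype2"})
        km = km_curve_table(km_estimate(records, groups))
        lr = logrank_test(records, groups)
        uni = cox_table(cox_fit(records, covariates, mode="univariate"))
        multi = cox_table(cox_fit(records, covariates, mode="multivariate"))
    return ValidationResult(assignment=assignment, association=association,
                            enrichment=enrichment, km_table=km, logrank=lr,
                            cox_univariate=uni, cox_multivariate=multi)


# ---------------------------------------------------------------------------
# file-based orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, outputs: list[Path],
                    inputs: list[Path]) -> Path:
    manifest = {
        "package": "lvisig",
        "version": __version__,
        "seed": config.seed,
        "config": {k: (asdict(v) if isinstance(v, ClusteringParams) else v)
                   for k, v in asdict(config).items()},
        "inputs": {str(p): _sha256(p) for p in inputs if p and Path(p).exists()},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    path = outdir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_discovery(config: RunConfig) -> GeneSignature:
    """File-based discovery stage; writes WAD tables, signature and manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with _stage("discovery:read"):
        expr_a = read_expression(config.expression_a)
        clin_a = read_clinical(config.clinical_a)
        expr_b = read_expression(config.expression_b)
        clin_b = read_clinical(config.clinical_b)
    result = run_discovery_frames(expr_a, clin_a, expr_b, clin_b, k=config.k,
                                  per_direction=config.per_direction)
    outputs = []
    for name, table in (("wad_discovery_a.tsv", result.wad_a),
                        ("wad_discovery_b.tsv", result.wad_b)):
        write_wad_table(table, outdir / name)
        outputs.append(outdir / name)
    sig_path = outdir / "signature.tsv"
    write_signature(result.signature, sig_path)
    outputs.append(sig_path)
    inputs = [Path(p) for p in (config.expression_a, config.clinical_a,
                                config.expression_b, config.clinical_b)]
    _write_manifest(outdir, config, outputs, inputs)
    logger.info("discovery: %d up + %d down genes -> %s",
                len(result.signature.up), len(result.signature.down), sig_path)
    return result.signature


def run_validation(config: RunConfig, signature: GeneSignature) -> ValidationResult:
    """File-based validation stage; writes assignments, tables and manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with _stage("validation:read"):
        expr = read_expression(config.expression_validation)
        clin = read_clinical(config.clinical_validation)
        database = read_gmt(config.gmt) if config.gmt else None
    result = run_validation_frames(
        expr, clin, signature, params=config.clustering, factors=config.factors,
        covariates=config.covariates or None, database=database, alpha=config.alpha)
    outputs = []

    def _save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(outdir / name, sep="\t", index=False,
                  lineterminator="\n", encoding="utf-8")
        outputs.append(outdir / name)

    assignments = pd.DataFrame({
        "sample_id": result.assignment.labels.index,
        "subtype": result.assignment.labels.to_numpy(),
        "score": result.assignment.scores.reindex(result.assignment.labels.index).to_numpy(),
    })
    _save(assignments, "subtype_assignments.tsv")
    _save(result.association, "association.tsv")
    if result.enrichment is not None:
        _save(result.enrichment, "enrichment.tsv")
    _save(result.km_table, "km_curves.tsv")
    _save(result.cox_univariate, "cox_univariate.tsv")
    _save(result.cox_multivariate, "cox_multivariate.tsv")
    stat, p = result.logrank
    with open(outdir / "logrank.json", "w", encoding="utf-8") as fh:
        json.dump({"statistic": stat, "p": p}, fh, indent=2)
        fh.write("\n")
    outputs.append(outdir / "logrank.json")
    inputs = [Path(p) for p in (config.expression_validation, config.clinical_validation,
                                config.gmt) if p]
    _write_manifest(outdir, config, outputs, inputs)
    return result
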