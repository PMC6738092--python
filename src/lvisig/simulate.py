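"""Synthetic cohorts with the statistical structure the LVI-signature analysis assumes.

The generator emulates a two-subgroup discovery design plus one validation
cohort.  A latent adverse ("genomic subtype 2") state — identified with
LVI-positivity, since in this model the subtype *is* the transcriptomic
fingerprint of LVI biology — drives three things:

* a log2 mean shift of +/- ``effect_size`` in the planted up/down genes,
* adverse clinical covariates (tumour size, nodal status, grade, ER/PR/HER2)
  drawn with subtype-conditional probabilities, and
* a proportional-hazards survival disadvantage (exponential baseline hazard,
  planted subtype-2 log hazard ratio, uniform accrual and administrative
  censoring).

Gene-level parameters (baseline means, planted gene identities) come from a
dedicated substream of the global seed, so all cohorts of one study share the
same genes, baselines and planted set while their samples are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple
from zlib import crc32

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ClinicalTable, ExpressionMatrix

#: default cohort sizes mirror the discovery (285 + 1280) / validation (854) design
DEFAULT_COHORT_SIZES = {"discovery-A": 285, "discovery-B": 1280, "validation": 854}

_COHORT_STREAMS = {"discovery-A": 1, "discovery-B": 2, "validation": 3}

#: P(adverse level | subtype 2), P(adverse level | subtype 1); contrasts chosen to
#: approximate the published METABRIC subtype table
DEFAULT_ADVERSE_PROBS: dict[str, tuple[float, float]] = {
    "tumour_size": (0.75, 0.62),
    "nodal_status": (0.52, 0.42),
    "grade": (0.73, 0.27),
    "er": (0.40, 0.04),
    "pr": (0.64, 0.28),
    "her2": (0.20, 0.03),
}

#: molecular-subtype composition per genomic subtype (normalised at draw time)
DEFAULT_MOLECULAR_PROBS: dict[int, dict[str, float]] = {
    1: {"LuminalA": 0.635, "LuminalB": 0.165, "HER2-enriched": 0.014,
        "Basal-like": 0.033, "Normal-like": 0.154},
    2: {"LuminalA": 0.153, "LuminalB": 0.329, "HER2-enriched": 0.207,
        "Basal-like": 0.269, "Normal-like": 0.042},
}

#: adverse level of each factor and the indicator name used in the hazard model
_ADVERSE_LEVEL = {
    "tumour_size": ("ge2cm", "lt2cm", "size_ge2cm"),
    "nodal_status": ("positive", "negative", "node_positive"),
    "grade": ("grade3", "grade1-2", "grade3"),
    "er": ("negative", "positive", "er_negative"),
    "pr": ("negative", "positive", "pr_negative"),
    "her2": ("positive", "negative", "her2_positive"),
}


@dataclass
class SimulationConfig:
    """Study-level generative parameters (log2 expression units, months)."""

    n_genes: int = 2000
    n_up: int = 30
    n_down: int = 30
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_SIZES))
    effect_size: float = 1.0          # log2 shift in LVI-positive samples
    baseline_range: tuple[float, float] = (4.0, 12.0)
    noise_sd: float = 1.0
    lvi_prevalence: float = 0.4
    covariate_adverse_probs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ADVERSE_PROBS))
    molecular_subtype_probs: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MOLECULAR_PROBS.items()})
    baseline_hazard: float = 0.0065   # events per month
    log_hazard_ratios: dict[str, float] = field(
        default_factory=lambda: {"subtype2": math.log(1.78)})
    admin_censoring: float = 180.0    # study close, months from study start
    accrual_window: float = 120.0     # uniform entry window, months
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not 0 < self.lvi_prevalence < 1:
            problems.append("lvi_prevalence must lie in (0, 1)")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be positive")
        lo, hi = self.baseline_range
        if not lo < hi:
            problems.append("baseline_range must satisfy lo < hi")
        if self.n_up + self.n_down > self.n_genes:
            problems.append("planted gene count exceeds n_genes")
        if self.n_up < 0 or self.n_down < 0:
            problems.append("planted gene counts must be non-negative")
        if self.baseline_hazard <= 0:
            problems.append("baseline_hazard must be positive")
        if self.admin_censoring <= self.accrual_window:
            problems.append("admin_censoring must exceed accrual_window")
        if any(n < 1 for n in self.cohort_sizes.values()):
            problems.append("cohort sizes must be >= 1")
        if problems:
            raise ValidationError("; ".join(problems))


@dataclass
class GroundTruth:
    """Planted structure for recovery oracles."""

    up_genes: list[str]
    down_genes: list[str]
    subtype: pd.Series            # per-sample latent subtype in {1, 2}
    linear_predictor: pd.Series   # per-sample true log relative hazard

    @property
    def planted(self) -> set[str]:
        return set(self.up_genes) | set(self.down_genes)


class Cohort(NamedTuple):
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth: GroundTruth


def _gene_level(config: SimulationConfig):
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    lo, hi = config.baseline_range
    baselines = rng.uniform(lo, hi, size=config.n_genes)
    planted = rng.choice(config.n_genes, size=config.n_up + config.n_down, replace=False)
    up_idx = np.sort(planted[:config.n_up])
    down_idx = np.sort(planted[config.n_up:])
    return genes, baselines, up_idx, down_idx


def simulate_cohort(config: SimulationConfig, cohort_name: str,
                    n_samples: int | None = None) -> Cohort:
    """One cohort (expression + clinical + ground truth), deterministic under the seed."""
    config.validate()
    genes, baselines, up_idx, down_idx = _gene_level(config)
    if n_samples is None:
        if cohort_name not in config.cohort_sizes:
            raise ValidationError(f"no configured size for cohort {cohort_name!r}")
        n_samples = config.cohort_sizes[cohort_name]
    stream = _COHORT_STREAMS.get(cohort_name, 10 + crc32(cohort_name.encode()) % 10_000)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=(stream,)))
    samples = [f"{cohort_name}-S{i:05d}" for i in range(1, n_samples + 1)]

    lvi_pos = rng.random(n_samples) < config.lvi_prevalence
    subtype = np.where(lvi_pos, 2, 1)

    expr = baselines[:, None] + rng.normal(0.0, config.noise_sd,
                                           size=(config.n_genes, n_samples))
    expr[np.ix_(up_idx, np.flatnonzero(lvi_pos))] += config.effect_size
    expr[np.ix_(down_idx, np.flatnonzero(lvi_pos))] -= config.effect_size

    clinical = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    clinical["lvi_status"] = np.where(lvi_pos, "positive", "negative")
    indicators: dict[str, np.ndarray] = {"subtype2": (subtype == 2).astype(float),
                                         "lvi_positive": lvi_pos.astype(float)}
    for factor, (p_sub2, p_sub1) in config.covariate_adverse_probs.items():
        adverse_level, other_level, indicator_name = _ADVERSE_LEVEL[factor]
        p = np.where(subtype == 2, p_sub2, p_sub1)
        adverse = rng.random(n_samples) < p
        clinical[factor] = np.where(adverse, adverse_level, other_level)
        indicators[indicator_name] = adverse.astype(float)

    mol = []
    for s in subtype:
        probs = config.molecular_subtype_probs[int(s)]
        names = list(probs)
        weights = np.asarray([probs[n] for n in names], dtype=float)
        mol.append(names[rng.choice(len(names), p=weights / weights.sum())])
    clinical["molecular_subtype"] = mol

    eta = np.zeros(n_samples)
    for name, coef in config.log_hazard_ratios.items():
        if name not in indicators:
            raise ValidationError(f"unknown hazard covariate {name!r}")
        eta += coef * indicators[name]
    rate = config.baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / rate)
    entry = rng.uniform(0.0, config.accrual_window, n_samples)
    censor_time = config.admin_censoring - entry
    observed = np.minimum(event_time, censor_time)
    died = event_time <= censor_time
    clinical["followup_time"] = observed
    clinical["event"] = np.where(died, "death", "censored")

    truth = GroundTruth(
        up_genes=[genes[i] for i in up_idx],
        down_genes=[genes[i] for i in down_idx],
        subtype=pd.Series(subtype, index=samples, name="subtype"),
        linear_predictor=pd.Series(eta, index=samples, name="linear_predictor"),
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples),
        platform_note=f"synthetic log2 expression, cohort {cohort_name}",
    )
    return Cohort(matrix, ClinicalTable(clinical), truth)


@dataclass
class StudyData:
    """Three named cohorts sharing one planted gene set."""

    cohorts: dict[str, Cohort]
    up_genes: list[str]
    down_genes: list[str]
    config: SimulationConfig

    @property
    def planted(self) -> set[str]:
        return set(self.up_genes) | set(self.down_genes)

    def __getitem__(self, name: str) -> Cohort:
        return self.cohorts[name]


def simulate_study(config: SimulationConfig | None = None) -> StudyData:
    """Two discovery subgroups plus a validation cohort under one seed."""
    config = config if config is not None else SimulationConfig()
    config.validate()
    cohorts = {name: simulate_cohort(config, name) for name in config.cohort_sizes}
    first = next(iter(cohorts.values()))
    return StudyData(cohorts=cohorts, up_genes=first.truth.up_genes,
                     down_genes=first.truth.down_genes, config=config)
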