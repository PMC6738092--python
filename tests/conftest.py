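"""Shared fixtures: hand-built toy matrices and small synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from lvisig import ClinicalTable, ExpressionMatrix, SimulationConfig, simulate_study


def make_matrix(values, genes, samples) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(np.asarray(values, dtype=float),
                                         index=genes, columns=samples))


@pytest.fixture
def toy_wad_matrix():
    """3 genes x 4 samples; groups of 2.  Hand-checkable WAD arithmetic:

    overall means 3, 1, 3 -> weights 1, 0, 1; AD 2, 2, 0 -> WAD 2, 0, 0.
    """
    matrix = make_matrix([[4, 4, 2, 2], [2, 2, 0, 0], [3, 3, 3, 3]],
                         ["A", "B", "C"], ["s1", "s2", "s3", "s4"])
    labels = pd.Series(["positive", "positive", "negative", "negative"],
                       index=["s1", "s2", "s3", "s4"])
    return matrix, labels


def make_clinical(n, seed=0, prefix="s") -> ClinicalTable:
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"{prefix}{i}" for i in range(n)], name="sample_id")
    df = pd.DataFrame(index=idx)
    df["lvi_status"] = rng.choice(["positive", "negative"], n)
    df["tumour_size"] = rng.choice(["ge2cm", "lt2cm"], n)
    df["nodal_status"] = rng.choice(["positive", "negative"], n)
    df["grade"] = rng.choice(["grade3", "grade1-2"], n)
    df["er"] = rng.choice(["positive", "negative"], n)
    df["pr"] = rng.choice(["positive", "negative"], n)
    df["her2"] = rng.choice(["positive", "negative"], n)
    df["molecular_subtype"] = rng.choice(["LuminalA", "LuminalB", "Basal-like"], n)
    df["followup_time"] = rng.uniform(1, 150, n)
    df["event"] = rng.choice(["death", "censored"], n)
    return ClinicalTable(df)


@pytest.fixture(scope="session")
def mini_study():
    """20 genes x 40 samples per subgroup, 6 planted with dominant WAD (pinned seed)."""
    cfg = SimulationConfig(n_genes=20, n_up=3, n_down=3,
                           cohort_sizes={"discovery-A": 40, "discovery-B": 40,
                                         "validation": 40},
                           effect_size=3.0, noise_sd=0.5, lvi_prevalence=0.5, seed=22)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def study_runs():
    """20 seeded studies under the default conditions; discovery + subtyping metrics."""
    from sklearn.metrics import adjusted_rand_score

    from lvisig.clustering import assign_subtypes
    from lvisig.pipeline import run_discovery_frames

    precision, recall, ari = [], [], []
    for seed in range(20):
        study = simulate_study(SimulationConfig(seed=seed))
        a, b = study["discovery-A"], study["discovery-B"]
        res = run_discovery_frames(a.expression, a.clinical, b.expression,
                                   b.clinical, k=350)
        discovered = set(res.signature.genes)
        true_pos = len(discovered & study.planted)
        precision.append(true_pos / len(discovered) if discovered else 0.0)
        recall.append(true_pos / len(study.planted))
        v = study["validation"]
        assignment = assign_subtypes(v.expression, res.signature)
        ari.append(adjusted_rand_score(v.truth.subtype.to_numpy(),
                                       assignment.labels.to_numpy()))
    return {"precision": precision, "recall": recall, "ari": ari}


@pytest.fixture(scope="session")
def small_study():
    """A fast full study (3 cohorts) with a clear but noisy planted signal."""
    cfg = SimulationConfig(n_genes=300, n_up=10, n_down=10,
                           cohort_sizes={"discovery-A": 80, "discovery-B": 120,
                                         "validation": 100},
                           effect_size=1.5, seed=5)
    return simulate_study(cfg)
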