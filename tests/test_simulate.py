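"""Synthetic-cohort generator: determinism, planted structure, recovery behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind

from lvisig import SimulationConfig, compute_wad, simulate_cohort, simulate_study
from lvisig.errors import ValidationError
from lvisig.pipeline import run_discovery_frames


def small_config(**kw):
    base = dict(n_genes=200, n_up=8, n_down=8,
                cohort_sizes={"discovery-A": 60, "discovery-B": 90, "validation": 50},
                seed=3)
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        c1 = simulate_cohort(small_config(), "discovery-A")
        c2 = simulate_cohort(small_config(), "discovery-A")
        pd.testing.assert_frame_equal(c1.expression.values, c2.expression.values)
        pd.testing.assert_frame_equal(c1.clinical.data, c2.clinical.data)
        pd.testing.assert_series_equal(c1.truth.subtype, c2.truth.subtype)

    def test_different_seeds_differ(self):
        c1 = simulate_cohort(small_config(seed=1), "discovery-A")
        c2 = simulate_cohort(small_config(seed=2), "discovery-A")
        assert not np.allclose(c1.expression.values, c2.expression.values)

    def test_cohorts_use_independent_sample_streams(self):
        study = simulate_study(small_config())
        a = study["discovery-A"].expression.values.to_numpy()
        b = study["discovery-B"].expression.values.to_numpy()
        assert not np.allclose(a[:, :50], b[:, :50])


class TestPlantedStructure:
    def test_default_cohort_sizes_mirror_study_design(self):
        cfg = SimulationConfig()
        assert cfg.cohort_sizes == {"discovery-A": 285, "discovery-B": 1280,
                                    "validation": 854}

    def test_planted_genes_shared_across_cohorts(self):
        study = simulate_study(small_config())
        for cohort in study.cohorts.values():
            assert set(cohort.truth.up_genes) == set(study.up_genes)
            assert set(cohort.truth.down_genes) == set(study.down_genes)

    def test_only_planted_genes_carry_group_shift(self):
        # near-noiseless cohort: group mean difference ~ +/- delta on planted, ~0 else
        cfg = small_config(noise_sd=1e-3, effect_size=1.0,
                           cohort_sizes={"discovery-A": 200})
        c = simulate_cohort(cfg, "discovery-A")
        labels = c.clinical.data["lvi_status"]
        t = compute_wad(c.expression, labels)
        assert np.allclose(t.loc[c.truth.up_genes, "ad"], 1.0, atol=0.01)
        assert np.allclose(t.loc[c.truth.down_genes, "ad"], -1.0, atol=0.01)
        rest = t.index.difference(c.truth.up_genes + c.truth.down_genes)
        assert np.abs(t.loc[rest, "ad"]).max() < 0.01

    def test_null_effect_makes_planted_indistinguishable(self):
        cfg = SimulationConfig(n_genes=1000, n_up=30, n_down=30, effect_size=0.0,
                               cohort_sizes={"discovery-A": 120}, seed=9)
        c = simulate_cohort(cfg, "discovery-A")
        t = compute_wad(c.expression, c.clinical.data["lvi_status"])
        planted = list(c.truth.planted)
        rest = t.index.difference(planted)
        res = ttest_ind(np.abs(t.loc[planted, "ad"]), np.abs(t.loc[rest, "ad"]))
        assert res.pvalue > 0.01

    def test_subtype_two_is_lvi_positive(self):
        c = simulate_cohort(small_config(), "validation")
        lvi = c.clinical.data["lvi_status"] == "positive"
        assert ((c.truth.subtype == 2) == lvi).all()

    def test_adverse_covariates_enriched_in_subtype_two(self):
        cfg = small_config(cohort_sizes={"validation": 2000})
        c = simulate_cohort(cfg, "validation")
        df = c.clinical.data
        sub2 = c.truth.subtype == 2
        for factor, adverse in [("grade", "grade3"), ("er", "negative"),
                                ("her2", "positive")]:
            rate2 = (df.loc[sub2.values, factor] == adverse).mean()
            rate1 = (df.loc[~sub2.values, factor] == adverse).mean()
            assert rate2 > rate1


class TestRecoveryMonotonicity:
    @staticmethod
    def recall(delta, n_a, n_b, seed, k=40):
        cfg = SimulationConfig(n_genes=400, n_up=10, n_down=10, effect_size=delta,
                               cohort_sizes={"discovery-A": n_a, "discovery-B": n_b},
                               seed=seed)
        study = simulate_study(cfg)
        a, b = study["discovery-A"], study["discovery-B"]
        res = run_discovery_frames(a.expression, a.clinical, b.expression,
                                   b.clinical, k=k)
        return len(set(res.signature.genes) & study.planted) / 20

    def test_recovery_non_decreasing_in_effect_size(self):
        lo = np.median([self.recall(0.25, 80, 120, s) for s in range(5)])
        hi = np.median([self.recall(1.5, 80, 120, s) for s in range(5)])
        assert hi >= lo

    def test_recovery_non_decreasing_in_sample_size(self):
        small = np.median([self.recall(0.6, 40, 60, s) for s in range(5)])
        large = np.median([self.recall(0.6, 200, 300, s) for s in range(5)])
        assert large >= small


class TestSurvivalGeneration:
    def test_null_hazard_ratio_recovered_near_one(self):
        from lvisig.survival import build_survival_records, cap_followup, cox_fit

        cfg = SimulationConfig(n_genes=10, n_up=0, n_down=0, log_hazard_ratios={},
                               cohort_sizes={"validation": 4000}, seed=4)
        c = simulate_cohort(cfg, "validation")
        rec = cap_followup(build_survival_records(c.clinical, c.truth.subtype))
        r = cox_fit(rec, ["subtype2"], mode="univariate")[0]
        assert abs(np.log(r.hr)) < 0.15
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_linear_predictor_matches_planted_coefficients(self):
        cfg = small_config()
        c = simulate_cohort(cfg, "validation")
        expected = np.log(1.78) * (c.truth.subtype == 2).to_numpy()
        assert np.allclose(c.truth.linear_predictor, expected)


class TestConfigValidation:
    def test_invalid_fields_enumerated(self):
        cfg = SimulationConfig(lvi_prevalence=1.5, noise_sd=-1.0,
                               baseline_range=(5.0, 2.0))
        with pytest.raises(ValidationError) as exc:
            cfg.validate()
        message = str(exc.value)
        assert "lvi_prevalence" in message and "noise_sd" in message \
            and "baseline_range" in message

    def test_planted_count_bounded_by_genes(self):
        with pytest.raises(ValidationError, match="planted"):
            SimulationConfig(n_genes=10, n_up=8, n_down=8).validate()
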