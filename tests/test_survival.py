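"""Survival analysis: follow-up capping, KM estimator, log-rank and Cox fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from lvisig import SimulationConfig, simulate_cohort
from lvisig.errors import DomainError, FitError, GroupSizeError
from lvisig.survival import (KMCurve, build_survival_records, cap_followup,
                             cox_fit, km_estimate, logrank_test)

from conftest import make_clinical


def records_from(times, events, x=None):
    df = pd.DataFrame({"time": times, "event": events},
                      index=[f"s{i}" for i in range(len(times))])
    if x is not None:
        df["x"] = x
    return df


class TestCapFollowup:
    def test_late_death_becomes_censored_at_cap(self):
        rec = cap_followup(records_from([150.0], [1]))
        assert rec.loc["s0", "time"] == 120.0 and rec.loc["s0", "event"] == 0

    def test_event_before_cap_unchanged(self):
        rec = cap_followup(records_from([119.0], [1]))
        assert rec.loc["s0", "time"] == 119.0 and rec.loc["s0", "event"] == 1

    def test_idempotent(self):
        rec = records_from([150.0, 60.0, 121.0], [1, 1, 0])
        once = cap_followup(rec)
        pd.testing.assert_frame_equal(once, cap_followup(once))


class TestKaplanMeier:
    def test_one_death_among_four(self):
        curve = km_estimate(records_from([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0]))["all"]
        assert curve.survival_at(1.0) == pytest.approx(0.75)

    def test_all_censored_flat_at_one(self):
        curve = km_estimate(records_from([1.0, 2.0, 3.0], [0, 0, 0]))["all"]
        assert (curve.survival == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=50)
        curve = km_estimate(records_from(times, [1] * 50))["all"]
        for t in (2.0, 5.0, 15.0):
            assert curve.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_exponential_simulation_matches_closed_form(self):
        cfg = SimulationConfig(n_genes=10, n_up=0, n_down=0, baseline_hazard=0.01,
                               log_hazard_ratios={}, admin_censoring=120.0,
                               accrual_window=1e-9,
                               cohort_sizes={"validation": 5000}, seed=2)
        cohort = simulate_cohort(cfg, "validation")
        curve = km_estimate(build_survival_records(cohort.clinical))["all"]
        assert curve.survival_at(60.0) == pytest.approx(np.exp(-0.6), abs=0.02)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        rec = records_from(rng.exponential(20, 100), rng.integers(0, 2, 100))
        curve = km_estimate(rec)["all"]
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert ((curve.survival >= 0) & (curve.survival <= 1)).all()

    def test_empty_group_rejected(self):
        rec = records_from([1.0, 2.0], [1, 1])
        groups = pd.Series(["a", None], index=rec.index)
        with pytest.raises(GroupSizeError):
            km_estimate(rec.iloc[:0])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 0, 1, 0]
        rec = records_from(times + times, events + events)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=rec.index)
        stat, p = logrank_test(rec, groups)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_strong_separation_significant(self):
        rng = np.random.default_rng(1)
        t_a = rng.exponential(1 / 0.01, 200)
        t_b = rng.exponential(1 / 0.05, 200)   # hazard ratio 5
        rec = records_from(np.concatenate([t_a, t_b]), [1] * 400)
        groups = pd.Series(["a"] * 200 + ["b"] * 200, index=rec.index)
        stat, p = logrank_test(rec, groups)
        assert p < 0.001

    def test_type_one_error_under_permutation(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(30, 60)
        events = (rng.random(60) < 0.7).astype(int)
        rec = records_from(times, events)
        base = np.array(["a"] * 30 + ["b"] * 30)
        rejections = 0
        n_perm = 1000
        for _ in range(n_perm):
            groups = pd.Series(rng.permutation(base), index=rec.index)
            _, p = logrank_test(rec, groups)
            rejections += p < 0.05
        assert rejections / n_perm == pytest.approx(0.05, abs=0.02)

    def test_needs_exactly_two_groups(self):
        rec = records_from([1.0, 2.0, 3.0], [1, 1, 1])
        groups = pd.Series(["a", "b", "c"], index=rec.index)
        with pytest.raises(GroupSizeError):
            logrank_test(rec, groups)


def neg_log_partial_likelihood(beta, times, events, x):
    """Hand-written Cox partial likelihood (distinct times): the grid oracle."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return -ll


class TestCox:
    def test_identical_groups_hazard_ratio_one(self):
        times = [2.0, 5.0, 9.0, 11.0]
        events = [1, 1, 0, 1]
        rec = records_from(times + times, events + events,
                           x=[0.0] * 4 + [1.0] * 4)
        r = cox_fit(rec, ["x"], mode="univariate")[0]
        assert r.hr == pytest.approx(1.0, abs=1e-6)
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_two_event_fit_matches_grid_search_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        rec = records_from(times, events, x=x)
        r = cox_fit(rec, ["x"], mode="univariate")[0]
        oracle = minimize_scalar(neg_log_partial_likelihood, bounds=(-5, 5),
                                 args=(times, events, x), method="bounded",
                                 options={"xatol": 1e-10})
        assert r.log_hr == pytest.approx(oracle.x, abs=1e-6)

    def test_time_scale_invariance(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(20, 80)
        events = (rng.random(80) < 0.8).astype(int)
        x = (rng.random(80) < 0.5).astype(float)
        r1 = cox_fit(records_from(times, events, x=x), ["x"])[0]
        r2 = cox_fit(records_from(times * 3.7, events, x=x), ["x"])[0]
        assert r1.hr == pytest.approx(r2.hr, rel=1e-8)

    def test_univariate_agrees_with_logrank_direction(self):
        rng = np.random.default_rng(9)
        t_a = rng.exponential(1 / 0.01, 150)
        t_b = rng.exponential(1 / 0.04, 150)
        rec = records_from(np.concatenate([t_a, t_b]), [1] * 300,
                           x=[0.0] * 150 + [1.0] * 150)
        r = cox_fit(rec, ["x"])[0]
        groups = pd.Series(["a"] * 150 + ["b"] * 150, index=rec.index)
        _, p_lr = logrank_test(rec, groups)
        assert r.hr > 1 and r.p < 0.01 and p_lr < 0.01

    def test_multivariate_joint_model_and_listwise_exclusion(self):
        rng = np.random.default_rng(4)
        n = 120
        rec = records_from(rng.exponential(30, n), (rng.random(n) < 0.7).astype(int))
        rec["a"] = (rng.random(n) < 0.5).astype(float)
        rec["b"] = (rng.random(n) < 0.5).astype(float)
        rec.loc[rec.index[:10], "b"] = np.nan
        results = cox_fit(rec, ["a", "b"], mode="multivariate")
        assert [r.covariate for r in results] == ["a", "b"]
        assert all(r.n == n - 10 for r in results)
        uni = cox_fit(rec, ["a", "b"], mode="univariate")
        assert uni[0].n == n and uni[1].n == n - 10

    def test_no_events_rejected(self):
        rec = records_from([1.0, 2.0], [0, 0], x=[0.0, 1.0])
        with pytest.raises(FitError):
            cox_fit(rec, ["x"])

    def test_unknown_covariate_name(self):
        rec = records_from([1.0, 2.0], [1, 0], x=[0.0, 1.0])
        with pytest.raises(DomainError):
            cox_fit(rec, ["zzz"])


class TestRecordBuilding:
    def test_adverse_level_coding(self):
        clin = make_clinical(30, seed=2)
        rec = build_survival_records(clin)
        assert (rec["grade3"] == (clin.data["grade"] == "grade3")).all()
        assert (rec["er_negative"] == (clin.data["er"] == "negative")).all()

    def test_unknown_becomes_nan(self):
        clin = make_clinical(10, seed=2)
        clin.data.loc[clin.data.index[0], "her2"] = "unknown"
        rec = build_survival_records(clin)
        assert np.isnan(rec["her2_positive"].iloc[0])

    def test_subtype_labels_merged(self):
        clin = make_clinical(10, seed=2)
        labels = pd.Series([1, 2] * 5, index=clin.data.index)
        rec = build_survival_records(clin, labels)
        assert (rec["subtype2"] == np.tile([0.0, 1.0], 5)).all()

    def test_nonpositive_time_rejected(self):
        clin = make_clinical(5, seed=2)
        clin.data.loc[clin.data.index[0], "followup_time"] = 0.0
        with pytest.raises(DomainError):
            build_survival_records(clin)
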