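import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

import immunoprofiler as ip

from oracles import (cox_mle_brute, km_brute, logrank_2group_brute,
                     maxsel_cutoff_brute)


def surv(times, events, ids=None):
    ids = ids or [f"P{i}" for i in range(len(times))]
    return pd.DataFrame({"sample_id": ids, "time": times, "event": events})


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        curve = ip.km_estimate(surv([1, 2, 3], [True, True, True]))
        np.testing.assert_allclose(curve.times, [1, 2, 3])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_shrinks_risk_set_without_step(self):
        curve = ip.km_estimate(surv([1, 2, 3], [True, False, True]))
        np.testing.assert_allclose(curve.times, [1, 3])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
        assert curve.survival_at(2.5) == pytest.approx(2 / 3)

    def test_all_censored_is_flat_one(self):
        curve = ip.km_estimate(surv([5, 8, 2], [False, False, False]))
        assert len(curve.times) == 0
        assert curve.survival_at(100) == 1.0

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        times = rng.integers(1, 10, size=40).astype(float)
        events = rng.random(40) < 0.7
        curve = ip.km_estimate(surv(times, events))
        t_ref, s_ref = km_brute(times, events)
        np.testing.assert_allclose(curve.times, t_ref)
        np.testing.assert_allclose(curve.survival, s_ref, rtol=1e-12)

    def test_nonpositive_time_is_error(self):
        with pytest.raises(ValueError):
            ip.km_estimate(surv([0.0, 1.0], [True, True]))


class TestLogrank:
    def test_identical_groups_are_null(self):
        g = surv([1, 3, 5, 7], [True, True, False, True])
        chi2, df, p = ip.logrank_test([g, g.assign(sample_id=lambda d: d.sample_id + "b")])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_and_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        times = rng.exponential(10, size=n) + 0.01
        events = rng.random(n) < 0.75
        group = rng.random(n) < 0.5
        if group.all() or not group.any():
            group[0] = ~group[0]
        g1 = surv(times[group], events[group], [f"A{i}" for i in range(group.sum())])
        g2 = surv(times[~group], events[~group], [f"B{i}" for i in range((~group).sum())])
        chi2, df, p = ip.logrank_test([g1, g2])
        _, _, chi2_ref, p_ref = logrank_2group_brute(times, events, group)
        assert chi2 == pytest.approx(chi2_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)
        ll = ll_logrank(times[group], times[~group], events[group], events[~group])
        assert chi2 == pytest.approx(ll.test_statistic, rel=1e-9)

    def test_three_group_statistic_defined(self):
        rng = np.random.default_rng(7)
        gs = [surv(rng.exponential(scale, 15), rng.random(15) < 0.8,
                   [f"{scale}_{i}" for i in range(15)]) for scale in (5, 10, 20)]
        chi2, df, p = ip.logrank_test(gs)
        assert df == 2
        assert chi2 > 0 and 0 < p < 1

    def test_invariant_to_monotone_time_transform(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(10, size=40) + 0.01
        events = rng.random(40) < 0.7
        group = np.arange(40) < 20
        base = ip.logrank_test([surv(times[group], events[group]),
                                surv(times[~group], events[~group],
                                     [f"B{i}" for i in range(20)])])
        warped = np.log1p(times) * 3.7
        trans = ip.logrank_test([surv(warped[group], events[group]),
                                 surv(warped[~group], events[~group],
                                      [f"B{i}" for i in range(20)])])
        assert base[0] == pytest.approx(trans[0], rel=1e-12)

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            ip.logrank_test([surv([1, 2], [True, True])])


def test_logrank_power_hr3():
    """Planted hazard ratio 3 at n=50/50: p < 0.01 in >= 95% of 200 runs."""
    hits = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        t1 = rng.exponential(30.0, size=50)
        t2 = rng.exponential(10.0, size=50)
        c = rng.exponential(100.0, size=100)
        times = np.concatenate([t1, t2])
        events = times <= c
        times = np.minimum(times, c) + 1e-9
        _, _, p = ip.logrank_test([
            surv(times[:50], events[:50]),
            surv(times[50:], events[50:], [f"B{i}" for i in range(50)])])
        hits += p < 0.01
    assert hits >= 190


class TestCox:
    def test_matches_brute_force_partial_likelihood(self):
        rng = np.random.default_rng(1)
        n = 40
        x = (rng.random(n) < 0.5).astype(float)
        times = rng.exponential(10 * np.exp(-0.9 * x))
        times += rng.uniform(0, 1e-6, size=n)  # no ties
        df = surv(times, [True] * n).assign(x=x)
        fit = ip.cox_fit(df, ["x"])
        beta_ref = cox_mle_brute(times.tolist(), [True] * n, x.tolist())
        assert fit.loc["x", "coef"] == pytest.approx(beta_ref, abs=1e-4)
        assert fit.loc["x", "HR"] == pytest.approx(np.exp(beta_ref), rel=1e-3)

    def test_constant_covariate_is_error(self):
        df = surv([1, 2, 3, 4], [True, True, False, True]).assign(x=1.0)
        with pytest.raises(ValueError, match="constant"):
            ip.cox_fit(df, ["x"])

    def test_parameter_recovery_log_hr(self):
        """True log-HR 0.7, n=300: mean estimate within +/-0.1 over 100 runs."""
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=300)
            t = rng.exponential(np.exp(-0.7 * x) * 20)
            c = rng.exponential(60, size=300)
            df = surv(np.minimum(t, c) + 1e-9, t <= c).assign(x=x)
            estimates.append(ip.cox_fit(df, ["x"]).loc["x", "coef"])
        assert np.mean(estimates) == pytest.approx(0.7, abs=0.1)

    def test_no_events_is_error(self):
        df = surv([1, 2, 3], [False] * 3).assign(x=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="no events"):
            ip.cox_fit(df, ["x"])


class TestOptimalCutoff:
    def test_two_planted_populations_cut_in_gap(self):
        # scores perfectly ordered with survival: low scores live long
        scores = pd.Series(np.concatenate([np.linspace(1, 2, 10), np.linspace(5, 6, 10)]),
                           index=[f"P{i}" for i in range(20)])
        times = np.concatenate([np.linspace(50, 60, 10), np.linspace(5, 10, 10)])
        res = ip.optimal_cutoff(scores, surv(times, [True] * 20))
        assert 2.0 <= res.cutoff < 5.0
        assert (res.groups == "high").sum() == 10

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = pd.Series(rng.normal(size=n), index=[f"P{i}" for i in range(n)])
        times = rng.exponential(10, size=n) + 0.01
        events = rng.random(n) < 0.8
        res = ip.optimal_cutoff(scores, surv(times, events))
        c_ref, z_ref = maxsel_cutoff_brute(scores.tolist(), times.tolist(),
                                           events.tolist(), minprop=0.1)
        assert res.cutoff == pytest.approx(c_ref)
        assert res.statistic == pytest.approx(z_ref, abs=1e-9)

    def test_minprop_half_allows_only_median_split(self):
        scores = pd.Series(np.arange(10.0), index=[f"P{i}" for i in range(10)])
        times = np.linspace(1, 10, 10)
        res = ip.optimal_cutoff(scores, surv(times, [True] * 10), minprop=0.5)
        assert res.cutoff == 4.0  # the only admissible cut: 5 vs 5
        assert (res.groups == "high").sum() == 5

    def test_all_equal_scores_is_error(self):
        scores = pd.Series(1.0, index=[f"P{i}" for i in range(12)])
        with pytest.raises(ValueError, match="no valid split"):
            ip.optimal_cutoff(scores, surv(np.arange(1.0, 13.0), [True] * 12))


class TestBootstrapCutoff:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        n = 40
        scores = pd.Series(rng.normal(size=n), index=[f"P{i}" for i in range(n)])
        data = surv(rng.exponential(10, n) + 0.01, rng.random(n) < 0.8)
        r1 = ip.bootstrap_cutoff_p(scores, data, n_boot=50, seed=7)
        r2 = ip.bootstrap_cutoff_p(scores, data, n_boot=50, seed=7)
        assert r1.bootstrap_p == r2.bootstrap_p
        np.testing.assert_array_equal(r1.replicate_p, r2.replicate_p)

    def test_excessive_skips_error(self):
        # nearly constant scores: most 36-sample replicates have no split
        scores = pd.Series([1.0] * 39 + [2.0], index=[f"P{i}" for i in range(40)])
        data = surv(np.arange(1.0, 41.0), [True] * 40)
        with pytest.raises((RuntimeError, ValueError)):
            ip.bootstrap_cutoff_p(scores, data, n_boot=50, seed=1)

    def test_strong_effect_small_p(self):
        """HR 4 across a planted threshold: bootstrap p < 0.05 in >= 90% of
        seeded runs."""
        hits = 0
        for seed in range(20):
            cfg = ip.simulate.survival_threshold_config(seed=seed, n=80, hazard_ratio=4.0)
            _, _, truth = ip.simulate.simulate_counts(cfg)
            tis = truth.set_index("sample_id")["expected_tis"]
            data = ip.simulate.simulate_survival(truth, cfg)
            res = ip.bootstrap_cutoff_p(tis, data, n_boot=60, seed=seed)
            hits += res.bootstrap_p < 0.05
        assert hits >= 18


class TestStratification:
    def test_composite_boundaries_are_strict(self):
        tis = {"a": 9.0, "b": 9.2, "c": 8.0, "d": 9.5}
        tmb = {"a": 100.0, "b": 254.0, "c": 150.0, "d": 80.0}
        labels = ip.stratify_composite(tis, tmb)
        assert labels["a"] == "TIS-lo/TMB-lo"  # exactly at both cuts -> low
        assert labels["b"] == "TIS-hi/TMB-hi"
        assert labels["c"] == "TIS-lo/TMB-hi"
        assert labels["d"] == "TIS-hi/TMB-lo"
        assert len(labels) == 4  # partition: every sample exactly one label

    def test_composite_missing_sample_error(self):
        with pytest.raises(ValueError, match="x"):
            ip.stratify_composite({"a": 1.0, "x": 2.0}, {"a": 1.0})

    def test_quartile_groups_linear_interpolation(self):
        s = pd.Series(np.arange(1.0, 9.0), index=list("abcdefgh"))
        labels = ip.quartile_groups(s)
        assert (labels == "high").sum() == 2
        assert (labels == "medium").sum() == 4
        assert (labels == "low").sum() == 2
        shifted = ip.quartile_groups(s + 100.0)
        assert (labels == shifted).all()

    def test_quartile_all_equal_is_all_medium(self):
        labels = ip.quartile_groups(pd.Series(5.0, index=list("abcd")))
        assert (labels == "medium").all()
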