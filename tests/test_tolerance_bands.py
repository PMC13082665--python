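"""Meta-analytic fits, prediction intervals, Tukey fences and the bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divbta.exceptions import InsufficientDataError
from divbta.simulator import ScenarioConfig, simulate_trial
from divbta.summary_stats import DivbtaEstimate, lncvr
from divbta.tolerance_bands import (
    MetaFit,
    bootstrap_bands,
    prediction_interval,
    random_effects_meta,
    select_reference_set,
    tukey_fences,
)


def _est(y, v, trial=None):
    return DivbtaEstimate(
        statistic_kind="lnCVR", estimate=y, sampling_variance=v, trial_id=trial
    )


def _simulated_reference_set(rng, k=175, n_per_arm=50):
    cfg = ScenarioConfig(n_per_arm=n_per_arm, iterations=1)
    ests = []
    for i in range(k):
        treatment, control = simulate_trial(cfg, rng)
        e = lncvr(treatment, control)
        e.trial_id = f"t{i}"
        ests.append(e)
    return ests


class TestRandomEffectsMeta:
    def test_identical_estimates_collapse(self):
        ests = [_est(0.2, 0.01, f"t{i}") for i in range(5)]
        with pytest.warns(UserWarning, match="identical"):
            fit = random_effects_meta(ests)
        assert fit.mean_effect == pytest.approx(0.2)
        assert fit.tau2 == 0.0

    def test_two_clusters_insufficient(self):
        ests = [_est(0.0, 0.01, "a"), _est(0.1, 0.01, "a"), _est(0.2, 0.01, "b")]
        with pytest.raises(InsufficientDataError):
            random_effects_meta(ests)

    def test_dl_matches_hand_computation(self):
        # y = {0.0, 0.1, -0.1, 0.3}, all v = 0.01:
        # Q = 8.75, C = 300, tau2 = (8.75 - 3)/300
        ests = [_est(y, 0.01, f"t{i}") for i, y in enumerate([0.0, 0.1, -0.1, 0.3])]
        fit = random_effects_meta(ests, tau2_method="dl")
        assert fit.tau2 == pytest.approx(5.75 / 300, rel=1e-9)
        assert fit.mean_effect == pytest.approx(0.075, rel=1e-9)
        assert fit.var_mean == pytest.approx((0.01 + fit.tau2) / 4, rel=1e-9)
        assert fit.df == 2  # k - 2
        assert fit.method == "standard"

    def test_dl_matches_statsmodels_oracle(self):
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(5)
        y = rng.normal(0.0, 0.3, 12)
        v = rng.uniform(0.01, 0.1, 12)
        fit = random_effects_meta(
            [_est(float(a), float(b), f"t{i}") for i, (a, b) in enumerate(zip(y, v))],
            tau2_method="dl",
        )
        res = combine_effects(y, v, method_re="dl")
        assert fit.tau2 == pytest.approx(res.tau2, rel=1e-8)
        assert fit.mean_effect == pytest.approx(res.mean_effect_re, rel=1e-8)

    def test_reml_recovers_known_tau2(self):
        rng = np.random.default_rng(9)
        tau2_true = 0.04
        v = np.full(400, 0.005)
        y = rng.normal(0.0, math.sqrt(tau2_true), 400) + rng.normal(0, np.sqrt(v))
        fit = random_effects_meta(
            [_est(float(a), float(b), f"t{i}") for i, (a, b) in enumerate(zip(y, v))]
        )
        assert fit.tau2 == pytest.approx(tau2_true, rel=0.25)

    def test_cluster_robust_engages_for_multi_estimate_trials(self):
        rng = np.random.default_rng(13)
        ests = []
        for i in range(10):
            for j in range(2):  # two time points per trial
                ests.append(_est(float(rng.normal(0, 0.2)), 0.02, f"t{i}"))
        fit = random_effects_meta(ests)
        assert fit.method == "cluster_robust"
        assert fit.k == 10
        assert fit.var_mean > 0
        assert 1 <= fit.df <= 9  # Satterthwaite df cannot exceed k - 1

    def test_cluster_robust_var_reflects_between_cluster_spread(self):
        # Duplicated estimates within clusters: robust var of the mean should
        # track the empirical between-cluster variance of cluster means.
        rng = np.random.default_rng(17)
        means = rng.normal(0, 0.3, 40)
        ests = []
        for i, m in enumerate(means):
            ests.extend([_est(float(m), 0.02, f"t{i}"), _est(float(m), 0.02, f"t{i}")])
        fit = random_effects_meta(ests)
        empirical = float(np.var(means, ddof=1)) / len(means)
        assert fit.var_mean == pytest.approx(empirical, rel=0.15)


class TestPredictionInterval:
    def test_zero_spread_collapses_to_point(self):
        fit = MetaFit(0.12, 0.0, 0.0, k=10, df=8, method="standard")
        band = prediction_interval(fit, 3.0)
        assert band.lower == band.upper == pytest.approx(0.12)

    def test_normal_limit_half_width(self):
        fit = MetaFit(0.0, 1.0, 0.0, k=10**7, df=1e9, method="standard")
        band = prediction_interval(fit, 3.0)
        assert band.upper == pytest.approx(3.000, abs=1e-3)

    def test_bands_nested_in_sigma_level(self):
        fit = MetaFit(-0.03, 0.02, 0.001, k=100, df=98, method="standard")
        b3 = prediction_interval(fit, 3.0)
        b4 = prediction_interval(fit, 4.0)
        assert b4.lower < b3.lower and b3.upper < b4.upper

    def test_df_below_one_rejected(self):
        fit = MetaFit(0.0, 0.02, 0.001, k=3, df=0.5, method="standard")
        with pytest.raises(InsufficientDataError):
            prediction_interval(fit, 3.0)

    def test_null_coverage_of_new_trial_true_effect(self):
        # Reference sets of k=175 null trials; a new trial's true lnCVR falls
        # inside the fitted 3-sigma band with frequency >= 0.995.
        m_star, tau = -0.035, 0.166
        covered = total = 0
        for s in range(30):
            rng = np.random.default_rng(100 + s)
            fit = random_effects_meta(_simulated_reference_set(rng))
            band = prediction_interval(fit, 3.0)
            thetas = rng.normal(m_star, tau, 150)
            covered += int(((thetas >= band.lower) & (thetas <= band.upper)).sum())
            total += 150
        assert covered / total >= 0.995

    def test_parametric_band_similar_to_tukey_inner_fences(self):
        # On the default simulated reference set the 3-sigma band and the
        # Tukey inner fences have comparable widths (ratio in [0.7, 1.3]).
        rng = np.random.default_rng(42)
        ests = _simulated_reference_set(rng)
        band = prediction_interval(random_effects_meta(ests), 3.0)
        inner, _ = tukey_fences([e.estimate for e in ests])
        ratio = (band.upper - band.lower) / (inner.upper - inner.lower)
        assert 0.7 <= ratio <= 1.3


class TestTukeyFences:
    def test_all_equal_medians_collapse(self):
        inner, outer = tukey_fences([0.05] * 6)
        assert inner.lower == inner.upper == outer.lower == outer.upper == 0.05

    def test_hand_computed_hinges(self):
        # n=5 sorted: hinges are medians of {-0.2,-0.1,0} and {0,0.1,0.2}
        inner, outer = tukey_fences([-0.2, -0.1, 0.0, 0.1, 0.2])
        assert inner.lower == pytest.approx(-0.4)
        assert inner.upper == pytest.approx(0.4)
        assert outer.lower == pytest.approx(-0.7)
        assert outer.upper == pytest.approx(0.7)

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            tukey_fences([0.0, 0.1, 0.2])

    @given(
        st.lists(st.floats(min_value=-5, max_value=5), min_size=4, max_size=30),
        st.floats(min_value=-10, max_value=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_translation_equivariance(self, values, shift):
        inner, outer = tukey_fences(values)
        inner2, outer2 = tukey_fences([v + shift for v in values])
        assert inner2.lower == pytest.approx(inner.lower + shift, abs=1e-9)
        assert outer2.upper == pytest.approx(outer.upper + shift, abs=1e-9)


class TestBootstrap:
    def test_identical_trials_give_zero_width_cis(self):
        ests = [_est(0.1, 0.02, f"t{i}") for i in range(6)]
        with pytest.warns(UserWarning):
            bb = bootstrap_bands(ests, n_boot=50, seed=1)
        assert bb.lower_ci[0] == pytest.approx(bb.lower_ci[1])
        assert bb.upper_ci[0] == pytest.approx(bb.upper_ci[1])

    def test_seed_determinism(self):
        rng = np.random.default_rng(23)
        ests = _simulated_reference_set(rng, k=20)
        a = bootstrap_bands(ests, n_boot=120, seed=77)
        b = bootstrap_bands(ests, n_boot=120, seed=77)
        assert a.lower_ci == b.lower_ci and a.upper_ci == b.upper_ci

    def test_ci_contains_full_sample_bound(self):
        # Percentile CIs of each bound contain the full-sample bound in
        # >= 90% of simulated reference sets.
        hits = 0
        n_sets = 15
        for s in range(n_sets):
            rng = np.random.default_rng(300 + s)
            ests = _simulated_reference_set(rng, k=30)
            bb = bootstrap_bands(ests, n_boot=200, seed=s)
            ok_low = bb.lower_ci[0] <= bb.full_band.lower <= bb.lower_ci[1]
            ok_up = bb.upper_ci[0] <= bb.full_band.upper <= bb.upper_ci[1]
            hits += ok_low and ok_up
        assert hits / n_sets >= 0.9


class TestReferenceFilter:
    def test_exclusion_rule(self):
        ests = [_est(0.0, 0.01, t) for t in ("a", "b", "c", "d")]
        pmap = {"a": 0.5, "b": 0.01, "c": 0.99, "d": None}
        kept = select_reference_set(ests, pmap)
        assert [e.trial_id for e in kept] == ["a"]
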