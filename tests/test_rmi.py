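"""Behavioral arm: rates, gains, CDFs, violation areas, permutation, BH."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from c1race.bayes import ModelSpec
from c1race.rmi import (
    InsufficientTrialsError,
    bh_correct,
    cluster_permutation_test,
    estimate_cdfs,
    exponential_null_test,
    interp_ecdf,
    performance_rates,
    redundancy_gain,
    rmi_violation_area,
    violation_area_from_grids,
)
from c1race.simulate import exgauss_cdf

SPEC = ModelSpec(draws=3000, warmup=500, seed=5)


def rt_frame(rows):
    df = pd.DataFrame(rows)
    df.setdefault = None
    return df


def make_rt_table(class_rts, participant="P01"):
    rows = []
    for stim, rts in class_rts.items():
        for rt in rts:
            rows.append(dict(participant=participant, group="G", stimulus=stim,
                             target_class="x", congruence="none",
                             is_target=stim != "standard",
                             rt_ms=rt, correct=rt is not None and not np.isnan(rt)))
    return pd.DataFrame(rows)


class TestPerformance:
    def test_perfect_detection(self):
        df = make_rt_table({"A_T": [400.0] * 10, "standard": [np.nan] * 40})
        rates = performance_rates(df)
        assert rates.hit_rate.iloc[0] == 1.0
        assert rates.false_positive_rate.iloc[0] == 0.0

    def test_nine_of_ten_targets(self):
        df = make_rt_table({"A_T": [400.0] * 9 + [np.nan],
                            "standard": [np.nan] * 40})
        assert performance_rates(df).hit_rate.iloc[0] == pytest.approx(0.9)

    def test_simulated_miss_rate_recovered_within_binomial_se(self):
        from c1race.simulate import RTSimConfig, simulate_rt_dataset
        n = 1250  # × 8 target cells = 10⁴ targets
        rt = simulate_rt_dataset(RTSimConfig(
            miss_rate=0.1, n_trials=n, n_participants=1, seed=8))
        rates = performance_rates(rt)
        n_targets = rates.n_targets.iloc[0]
        se = np.sqrt(0.9 * 0.1 / n_targets)
        assert abs(rates.hit_rate.iloc[0] - 0.9) < 3 * se

    def test_no_targets_errors(self):
        df = make_rt_table({"standard": [np.nan] * 5})
        with pytest.raises(ValueError, match="no target"):
            performance_rates(df)


class TestRedundancyGain:
    def fixed_table(self, av_mean):
        return make_rt_table({
            "A_T": [500.0] * 4, "AT_V0": [520.0] * 4,
            "V_T": [450.0] * 4, "A0_VT": [480.0] * 4,
            "AT_VT": [av_mean] * 4,
        })

    def test_min_of_means_arithmetic(self):
        gains = redundancy_gain(self.fixed_table(400.0), scope="group")
        assert gains.gain_av_ms.iloc[0] == pytest.approx(50.0)

    def test_zero_gain_when_av_matches_fastest(self):
        gains = redundancy_gain(self.fixed_table(450.0), scope="group")
        assert gains.gain_av_ms.iloc[0] == pytest.approx(0.0)

    def test_empty_class_errors(self):
        df = make_rt_table({"A_T": [500.0], "AT_VT": [400.0]})
        with pytest.raises(ValueError, match="empty RT class"):
            redundancy_gain(df, scope="group")

    def test_coactivation_gain_matches_population_arithmetic(self):
        """Gain estimated from a large coactivation simulation agrees with
        the min-of-means computed from an independent Monte-Carlo of the
        same generative model."""
        from c1race.simulate import RTSimConfig, simulate_rt_dataset
        params = {"A": (350.0, 60.0, 120.0), "V": (400.0, 60.0, 120.0)}
        cfg = RTSimConfig(model="coactivation", coactivation_shift=40.0,
                          channel_params=params, miss_rate=0.0,
                          participant_jitter=0.0, n_participants=1,
                          n_trials=5000, seed=30)
        est = redundancy_gain(simulate_rt_dataset(cfg), scope="group")
        rng = np.random.default_rng(424242)
        n = 400_000
        t_a = 350 + 60 * rng.standard_normal(n) + 120 * rng.standard_exponential(n)
        t_v = 400 + 60 * rng.standard_normal(n) + 120 * rng.standard_exponential(n)
        oracle_gain = min(t_a.mean(), t_v.mean()) - (np.minimum(t_a, t_v) - 40).mean()
        sem = np.sqrt(2) * 170.0 / np.sqrt(10_000)  # conservative class SEM
        assert abs(est.gain_av_ms.iloc[0] - oracle_gain) < 3 * sem


class TestCDFEstimation:
    def test_median_of_three_by_linear_interpolation(self):
        triple = estimate_cdfs([400, 500, 600], [400, 500, 600],
                               [400, 500, 600], percentiles=(50,), min_trials=3)
        assert triple.t[0] == pytest.approx(500.0)

    def test_identical_rts_give_step_cdf(self):
        f = interp_ecdf(np.full(5, 300.0), [299.0, 300.0, 301.0])
        assert f[0] == 0.0 and f[1] == 1.0 and f[2] == 1.0

    def test_exponential_quantile_within_standard_error(self):
        rng = np.random.default_rng(77)
        sample = rng.exponential(200.0, 10_000)
        q25 = np.quantile(sample, 0.25)  # the estimator estimate_cdfs uses
        true_q = -200.0 * np.log(0.75)
        dens = (1 / 200.0) * 0.75
        se = np.sqrt(0.25 * 0.75 / sample.size) / dens
        assert abs(q25 - true_q) < 3 * se

    def test_insufficient_trials_flagged(self):
        with pytest.raises(InsufficientTrialsError):
            estimate_cdfs([400.0] * 3, [400.0] * 20, [400.0] * 20)


class TestViolationArea:
    def test_bound_met_with_equality_gives_zero_area(self):
        t = np.linspace(0, 1000, 2001)
        fa = exgauss_cdf(t, 300, 30, 100)
        fv = exgauss_cdf(t, 350, 40, 80)
        fav = np.minimum(1.0, fa + fv)
        assert violation_area_from_grids(t, fa, fv, fav) == pytest.approx(
            0.0, abs=1e-12)

    def test_rectangular_excess_integrates_to_rectangle(self):
        # excess ≈ 0.1 over a 50 ms stretch: fine grid keeps the trapezoid
        # edge-bin error below 1% of the 5 ms rectangle
        t = np.arange(0.0, 201.0, 0.1)
        fv = np.zeros_like(t)
        fav = np.maximum.accumulate(
            np.where((t >= 100) & (t <= 150), 0.1, 0.0))
        fa_after = np.where(t > 150, 0.1, 0.0)  # bound catches up after 150
        assert violation_area_from_grids(t, fa_after, fv, fav) == pytest.approx(
            5.0, abs=0.02)

    def test_trapezoid_matches_adaptive_quadrature_oracle(self):
        """Coactivated min-distribution vs independent exponential channels:
        the gridded trapezoid area agrees with adaptive quadrature to
        10⁻³ ms."""
        lam_a, lam_v, shift = 1 / 250.0, 1 / 300.0, 20.0

        def fa(t):
            return np.clip(1 - np.exp(-lam_a * np.maximum(t, 0)), 0, 1)

        def fv(t):
            return np.clip(1 - np.exp(-lam_v * np.maximum(t, 0)), 0, 1)

        def fmin(t):
            return fa(t) + fv(t) - fa(t) * fv(t)

        def fav(t):
            return fmin(np.asarray(t) + shift)

        t = np.arange(0.0, 3000.0, 0.25)
        area = violation_area_from_grids(t, fa(t), fv(t), fav(t))
        oracle, err = integrate.quad(
            lambda x: max(fav(x) - fa(x) - fv(x), 0.0), 0.0, 3000.0,
            limit=400)
        assert err < 1e-6
        assert area == pytest.approx(oracle, abs=1e-3)

    def test_non_monotone_cdf_rejected(self):
        t = np.arange(5.0)
        good = np.array([0.0, 0.2, 0.4, 0.6, 0.8])
        bad = np.array([0.0, 0.5, 0.3, 0.6, 0.8])
        with pytest.raises(ValueError, match="non-monotone"):
            violation_area_from_grids(t, good, good, bad)

    def test_area_invariant_to_common_time_shift(self):
        rng = np.random.default_rng(11)
        a = rng.exponential(200, 400) + 150
        v = rng.exponential(250, 400) + 150
        av = np.minimum(rng.exponential(200, 400) + 150,
                        rng.exponential(250, 400) + 150) - 25
        t0 = estimate_cdfs(a, v, av)
        t1 = estimate_cdfs(a + 500, v + 500, av + 500)
        assert rmi_violation_area(t1) == pytest.approx(
            rmi_violation_area(t0), rel=1e-9)


class TestClusterPermutation:
    def test_all_zero_profiles_report_no_violation(self):
        res = cluster_permutation_test(np.zeros((10, 6)), n_perm=101)
        assert res["clusters"] == []
        assert not res["significant"]

    def test_uniform_positive_profiles_reach_minimal_p(self):
        profiles = np.full((12, 6), 10.0)
        res = cluster_permutation_test(profiles, n_perm=10_001, seed=0)
        # only all-positive sign patterns tie the observed mass
        assert res["min_p"] < 1e-3
        assert res["significant"]

    def test_monte_carlo_p_matches_exhaustive_enumeration(self):
        """Sign-flip p-value at n=8 agrees with exact enumeration of all
        2⁸ sign patterns within Monte-Carlo error."""
        rng = np.random.default_rng(9)
        profiles = rng.normal(0.08, 0.1, size=(8, 6))
        n, k = profiles.shape
        threshold = stats.t.ppf(0.95, df=n - 1)

        def max_mass(x):
            mean = x.mean(axis=0)
            sd = x.std(axis=0, ddof=1)
            t = np.divide(mean, sd / np.sqrt(n), out=np.zeros(k),
                          where=sd > 0)
            best = run = 0.0
            for tj in t:
                run = run + tj if tj > threshold else 0.0
                best = max(best, run)
            return best

        obs = max_mass(profiles)
        exact_ge = sum(
            max_mass(np.asarray(signs)[:, None] * profiles) >= obs - 1e-12
            for signs in itertools.product((-1.0, 1.0), repeat=n))
        p_exact = exact_ge / 2**n

        res = cluster_permutation_test(profiles, n_perm=10_001, seed=123)
        p_mc = res["min_p"] if res["clusters"] else 1.0
        se = np.sqrt(p_exact * (1 - p_exact) / 10_001)
        assert abs(p_mc - p_exact) < 4 * se + 2e-4

    def test_degenerate_single_participant_rejected(self):
        with pytest.raises(ValueError, match="participants"):
            cluster_permutation_test(np.ones((1, 6)))


class TestBH:
    def test_stepup_rule_on_fixed_vector(self):
        # sorted p (.01,.02,.04,.8) at q=.05: k/m·q = .0125,.025,.0375,.05 →
        # largest k with p_(k) ≤ k/m·q is 2
        reject, p_adj = bh_correct([0.01, 0.02, 0.04, 0.80], q=0.05)
        assert list(reject) == [True, True, False, False]
        assert np.all(np.diff(p_adj[np.argsort([0.01, 0.02, 0.04, 0.80])]) >= 0)

    def test_single_p_reduces_to_alpha_test(self):
        reject, _ = bh_correct([0.03], q=0.05)
        assert reject[0]

    def test_all_ones_reject_nothing(self):
        reject, _ = bh_correct([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()

    def test_matches_brute_force_threshold_search(self, rng):
        for _ in range(200):
            m = rng.integers(1, 12)
            p = rng.uniform(1e-4, 1.0, size=m)
            reject, _ = bh_correct(p, q=0.05)
            # brute force: largest threshold t ∈ {p_i} with #{p ≤ t} ≥ m t / q
            candidates = [t for t in p
                          if t <= (np.sum(p <= t)) / m * 0.05]
            t_star = max(candidates, default=0.0)
            assert set(np.flatnonzero(reject)) == set(
                np.flatnonzero(p <= t_star))

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_correct([])
        with pytest.raises(ValueError):
            bh_correct([0.0, 0.5])


class TestExponentialNull:
    def test_all_zero_areas_favor_null(self):
        areas = pd.DataFrame({"participant": [f"P{i}" for i in range(6)],
                              "violation_area_ms": 0.0})
        res = exponential_null_test(areas, SPEC)
        row = res.summary.iloc[0]
        assert row.bf_10 == 0.0
        assert row.decision_two_sided == "absent-evidence"

    def test_clear_violations_yield_strong_evidence(self):
        rng = np.random.default_rng(15)
        areas = pd.DataFrame({
            "participant": [f"P{i}" for i in range(12)],
            "violation_area_ms": 25.0 + rng.exponential(10.0, 12)})
        res = exponential_null_test(areas, SPEC)
        row = res.summary.iloc[0]
        assert row.bf_10 > 3
        assert row.hdi_low > row.rope_halfwidth

    def test_group_difference_detected_by_factorial_model(self):
        rng = np.random.default_rng(16)
        rows = []
        for g, mu in (("CC", 10.0), ("MCC", 60.0)):
            for i in range(12):
                for cong in ("congruent", "incongruent"):
                    rows.append(dict(participant=f"{g}{i}", group=g,
                                     congruence=cong,
                                     violation_area_ms=max(
                                         rng.normal(mu, 8.0), 0.0)))
        res = exponential_null_test(pd.DataFrame(rows), SPEC)
        grp = res.summary[res.summary.parameter == "group"].iloc[0]
        assert grp.bf_10 > 3

    def test_constant_nonzero_areas_rejected(self):
        areas = pd.DataFrame({"participant": [f"P{i}" for i in range(6)],
                              "violation_area_ms": 5.0})
        with pytest.raises(ValueError, match="zero variance"):
            exponential_null_test(areas, SPEC)
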