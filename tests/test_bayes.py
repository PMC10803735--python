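"""Posterior inference: recovery, Savage–Dickey oracle, ROPE, trend."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from c1race.bayes import (
    ContrastSpec,
    ModelSpec,
    bayes_factor_directional,
    default_contrasts,
    fit_cell_means,
    linear_trend_test,
    rope_test,
)
from c1race.bayes import test_contrasts as run_contrast_model

SPEC = ModelSpec(draws=4000, warmup=500, seed=7)


def make_table(cell_means, n_participants=15, noise_sd=1.0,
               participant_sd=0.3, electrodes=("O1",), group="CC", seed=0):
    """ΔC1 table with known cell means per condition (same at every
    electrode unless a dict of dicts is given)."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        offset = participant_sd * rng.standard_normal()
        for cond, mu in cell_means.items():
            for e in electrodes:
                rows.append(dict(
                    participant=f"{group}{p:02d}", group=group, condition=cond,
                    electrode=e,
                    delta_c1=mu + offset + noise_sd * rng.standard_normal()))
    return pd.DataFrame(rows)


class TestCellMeans:
    def test_recovers_true_cell_mean_inside_hdi(self):
        table = make_table({"V": 2.0, "AV_i": 2.0, "AV_c": 2.0})
        res = fit_cell_means(table, SPEC)
        row = res.summary[res.summary.parameter == "CC:V:O1"].iloc[0]
        assert row.hdi_low < 2.0 < row.hdi_high
        assert abs(row["mean"] - 2.0) < 0.5

    def test_all_zero_responses_concentrate_at_zero(self):
        table = make_table({"V": 0.0}, noise_sd=0.0, participant_sd=0.0)
        res = fit_cell_means(table, SPEC)
        row = res.summary.iloc[0]
        # prior scale falls back to 1.0 for a degenerate response
        assert abs(row["mean"]) < 0.1 * row.prior_sd

    def test_scale_equivariance_of_data_scaled_priors(self):
        table = make_table({"V": 1.0, "AV_i": 0.5, "AV_c": 0.2})
        res1 = fit_cell_means(table, SPEC)
        doubled = table.assign(delta_c1=2 * table.delta_c1)
        res2 = fit_cell_means(doubled, SPEC)
        m1 = res1.summary.set_index("parameter")["mean"]
        m2 = res2.summary.set_index("parameter")["mean"]
        assert np.allclose(2 * m1, m2, rtol=1e-10)

    def test_requires_two_participants(self):
        table = make_table({"V": 1.0}, n_participants=1)
        with pytest.raises(ValueError, match="participants"):
            fit_cell_means(table, SPEC)

    def test_fixed_seed_reproduces_inference(self):
        table = make_table({"V": 1.0, "AV_c": 0.0})
        a = fit_cell_means(table, SPEC)
        b = fit_cell_means(table, SPEC)
        pd.testing.assert_frame_equal(a.summary, b.summary)


class TestSavageDickey:
    def test_matches_conjugate_closed_form_over_effect_grid(self):
        """Normal–normal conjugate case with known σ: the density-ratio BF
        from draws agrees with the analytic BF within 5%."""
        prior_sd, sigma, n = 2.0, 1.0, 20
        rng = np.random.default_rng(42)
        for eff in (0.0, 0.2, 0.4, 0.6, 0.8):
            v = 1.0 / (n / sigma**2 + 1.0 / prior_sd**2)
            m = v * n * eff / sigma**2
            draws = m + np.sqrt(v) * rng.standard_normal(200_000)
            bf_plus0, bf10 = bayes_factor_directional(draws, prior_sd)
            bf10_true = stats.norm.pdf(0, scale=prior_sd) / stats.norm.pdf(
                0, loc=m, scale=np.sqrt(v))
            bfp_true = bf10_true * stats.norm.sf(
                0, loc=m, scale=np.sqrt(v)) / 0.5
            assert bf10 == pytest.approx(bf10_true, rel=0.05)
            assert bf_plus0 == pytest.approx(bfp_true, rel=0.05)

    def test_no_data_prior_equals_posterior_gives_bf_one(self):
        rng = np.random.default_rng(3)
        draws = 2.0 * rng.standard_normal(100_000)  # draws from the prior
        _, bf10 = bayes_factor_directional(draws, 2.0)
        assert bf10 == pytest.approx(1.0, rel=0.05)

    def test_overwhelming_evidence_gives_huge_directional_bf(self):
        draws = 20.0 + 1.0 * np.random.default_rng(4).standard_normal(50_000)
        with pytest.warns(RuntimeWarning, match="few posterior draws"):
            bf_plus0, _ = bayes_factor_directional(draws, 2.0)
        assert bf_plus0 > 1e6

    def test_invalid_prior_sd_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor_directional(np.zeros(10) + 1.0, 0.0)


class TestRope:
    def test_point_mass_outside_rope(self):
        res = rope_test(np.full(1000, 1.0), 0.2)
        assert res["outside_rope"] and not res["inside_rope"]

    def test_tight_null_inside_rope(self):
        draws = 0.01 * np.random.default_rng(0).standard_normal(20_000)
        res = rope_test(draws, 0.2)
        assert res["inside_rope"]
        assert res["frac_hdi_in_rope"] == 1.0

    def test_normal_quantile_hdi_overlapping_rope_is_undecided(self):
        # HDI ≈ [0.152, 0.348] against ROPE [−0.2, 0.2]: neither fully
        # outside nor fully inside, so the full-exclusion rule withholds
        draws = 0.25 + 0.05 * np.random.default_rng(1).standard_normal(100_000)
        res = rope_test(draws, 0.2)
        assert res["hdi_low"] == pytest.approx(0.152, abs=0.01)
        assert res["hdi_high"] == pytest.approx(0.348, abs=0.01)
        assert not res["outside_rope"] and not res["inside_rope"]
        assert 0.1 < res["frac_hdi_in_rope"] < 0.4

    def test_hdi_fully_clear_of_rope_passes(self):
        draws = 0.45 + 0.05 * np.random.default_rng(2).standard_normal(100_000)
        res = rope_test(draws, 0.2)
        assert res["outside_rope"]
        assert res["frac_hdi_in_rope"] == 0.0

    def test_non_finite_draws_rejected(self):
        with pytest.raises(ValueError):
            rope_test(np.array([0.1, np.nan]), 0.2)


class TestContrasts:
    def two_group_table(self, cc_means, mcc_means, seed=0):
        cc = make_table(cc_means, group="CC", seed=seed,
                        electrodes=("O1", "O2", "P3", "P4", "Pz"))
        mcc = make_table(mcc_means, group="MCC", seed=seed + 1,
                         electrodes=("O1", "O2", "P3", "P4", "Pz"))
        return pd.concat([cc, mcc], ignore_index=True)

    def test_suppressed_condition_contrast_flagged_substantial(self):
        table = self.two_group_table(
            {"V": 2.0, "AV_i": 1.0, "AV_c": 0.0},
            {"V": 2.0, "AV_i": 2.0, "AV_c": 2.0})
        res = run_contrast_model(table, spec=SPEC)
        row = res.summary[res.summary.parameter == "O1:CC:V-CC:AV_c"].iloc[0]
        assert row.substantial
        assert row["mean"] == pytest.approx(2.0, abs=0.6)

    def test_equal_cells_not_substantial(self):
        table = self.two_group_table(
            {"V": 1.0, "AV_i": 1.0, "AV_c": 1.0},
            {"V": 1.0, "AV_i": 1.0, "AV_c": 1.0})
        res = run_contrast_model(table, spec=SPEC)
        assert not res.summary.substantial.any()
        assert (res.summary.bf_10 < 3).all()

    def test_rank_deficient_contrast_rejected(self):
        cells = tuple(("CC", c) for c in ("V", "AV_i", "AV_c"))
        with pytest.raises(ValueError, match="rank deficient"):
            ContrastSpec(("self",), cells, np.zeros((1, 3)))

    def test_default_contrast_matrix_is_full_rank_with_completion(self):
        spec = default_contrasts()
        stacked = np.vstack([np.full((1, 6), 1 / 6), spec.matrix])
        assert np.linalg.matrix_rank(stacked) == 6


class TestLinearTrend:
    def electrodes(self):
        return ("O1", "O2", "P3", "P4", "Pz")

    def test_graded_suppression_recovers_negative_linear_component(self):
        table = make_table({"V": 2.0, "AV_i": 1.0, "AV_c": 0.0},
                           electrodes=self.electrodes(), noise_sd=0.5)
        res = linear_trend_test(table, SPEC)
        lin = res.summary[res.summary.parameter == "linear"].iloc[0]
        assert lin.bf_10 > 10
        assert lin["mean"] < 0
        assert lin.decision_two_sided == "present"

    def test_flat_profile_shows_no_trend(self):
        table = make_table({"V": 1.0, "AV_i": 1.0, "AV_c": 1.0},
                           electrodes=self.electrodes(), noise_sd=0.5)
        res = linear_trend_test(table, SPEC)
        lin = res.summary[res.summary.parameter == "linear"].iloc[0]
        assert lin.bf_10 < 1.0

    def test_v_shape_loads_on_quadratic_not_linear(self):
        table = make_table({"V": 0.0, "AV_i": 1.0, "AV_c": 0.0},
                           electrodes=self.electrodes(), noise_sd=0.2)
        res = linear_trend_test(table, SPEC)
        lin = res.summary[res.summary.parameter == "linear"].iloc[0]
        quad = res.summary[res.summary.parameter == "quadratic"].iloc[0]
        assert abs(lin["mean"]) < 0.15
        assert quad.bf_10 > 10

    def test_missing_level_rejected(self):
        table = make_table({"V": 1.0, "AV_i": 1.0},
                           electrodes=self.electrodes())
        with pytest.raises(ValueError, match="missing condition"):
            linear_trend_test(table, SPEC)


def test_present_rate_monotone_in_true_effect():
    """Decision-rule monotonicity: a larger simulated ΔC1 never lowers the
    rate of 'present' decisions (3-point effect grid)."""
    rates = []
    for effect in (0.0, 0.6, 1.5):
        present = 0
        reps = 12
        for r in range(reps):
            table = make_table({"V": effect}, n_participants=10,
                               noise_sd=0.5, seed=1000 * r + int(effect * 10))
            res = fit_cell_means(table, ModelSpec(draws=1200, warmup=300, seed=r))
            present += (res.summary.iloc[0].decision_one_sided == "present")
        rates.append(present / reps)
    assert rates[0] <= rates[1] + 1e-9 <= rates[2] + 2e-9
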