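"""Bridging-coefficient estimation, GC correction and the MR-G×E screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrgxe import (
    DegenerateInstrumentsError, HarmonizedPanel, TableLD,
    estimate_overlap_corr, expected_theta, gc_lambda, imrp_estimate,
    interaction_effect_mr, ivw_theta, screen_panel, select_instruments,
    simulate_null_sumstat_panel, t_mr_gxe, t_mr_gxe_arrays,
)


class TestGcLambda:
    def test_definition_at_the_chi2_median(self):
        assert gc_lambda([0.4549] * 7) == pytest.approx(1.0, abs=1e-3)

    def test_null_draws_give_unit_lambda(self):
        rng = np.random.default_rng(0)
        chisq = rng.chisquare(1, 100_000)
        assert gc_lambda(chisq) == pytest.approx(1.0, abs=0.02)

    def test_scaled_draws_scale_lambda(self):
        rng = np.random.default_rng(1)
        chisq = 2.0 * rng.chisquare(1, 100_000)
        assert gc_lambda(chisq) == pytest.approx(2.0, abs=0.05)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            gc_lambda([])


def _significant_panel(entries):
    """Panel of (id, chrom, pos, p_gwas) with strong matching z-scores."""
    rows = []
    for vid, chrom, pos, p in entries:
        z = np.sqrt(stats.chi2.isf(p, 1))
        rows.append({"variant_id": vid, "chrom": chrom, "pos": pos,
                     "effect_allele": "A", "other_allele": "G",
                     "alpha_hat": z * 0.01, "se_alpha": 0.01, "p_gwas": p,
                     "n1": 1e5, "eaf_gwas": 0.3,
                     "beta1_hat": z * 0.01, "se_beta1": 0.012,
                     "beta3_hat": 0.0, "se_beta3": 0.01,
                     "p_gwis": 0.5, "n2": 3e4, "eaf_gwis": 0.3})
    return HarmonizedPanel(pd.DataFrame(rows))


class TestSelectInstruments:
    def test_ld_pruning_keeps_most_significant(self):
        panel = _significant_panel([
            ("rs1", "1", 1_000_000, 1e-20), ("rs2", "1", 1_100_000, 1e-10),
            ("rs3", "2", 1_000_000, 1e-15)])
        ld = TableLD(pd.DataFrame({"id1": ["rs1"], "id2": ["rs2"], "r2": [0.5]}))
        out = select_instruments(panel, ld=ld, apply_gc=False)
        assert set(out.df["variant_id"]) == {"rs1", "rs3"}

    def test_outside_window_both_kept(self):
        panel = _significant_panel([
            ("rs1", "1", 1_000_000, 1e-20), ("rs2", "1", 1_600_000, 1e-10),
            ("rs3", "2", 1_000_000, 1e-15)])
        ld = TableLD(pd.DataFrame({"id1": ["rs1"], "id2": ["rs2"], "r2": [0.9]}))
        out = select_instruments(panel, ld=ld, apply_gc=False)
        assert len(out) == 3

    def test_gc_correction_pushes_borderline_out(self):
        # inflated chi-squares: borderline variant crosses 5e-8 after GC
        borderline_p = 2e-8
        entries = [("rs1", "1", 1_000_000, 1e-30),
                   ("rs2", "2", 1_000_000, borderline_p),
                   ("rs3", "3", 1_000_000, 1e-30)]
        # pad with null-ish variants whose chi-square is ~1.5 (lambda > 1)
        entries += [(f"pad{i}", "4", 1_000_000 + i * 10**6,
                     float(stats.chi2.sf(1.5, 1))) for i in range(200)]
        panel = _significant_panel(entries)
        out = select_instruments(panel, apply_gc=True)
        assert out.gc_lam > 1
        assert "rs2" not in set(out.df["variant_id"])
        out_nogc = select_instruments(panel, apply_gc=False)
        assert "rs2" in set(out_nogc.df["variant_id"])

    def test_fewer_than_two_instruments_raises(self):
        panel = _significant_panel([("rs1", "1", 1, 1e-20),
                                    ("rs2", "1", 2, 0.5)])
        with pytest.raises(DegenerateInstrumentsError):
            select_instruments(panel, apply_gc=False)


class TestOverlapCorr:
    def test_identical_z_scores_give_unit_correlation(self):
        panel = simulate_null_sumstat_panel(500, 10_000, 10_000, seed=3)
        df = panel.df.copy()
        df["beta1_hat"] = df["alpha_hat"]
        df["se_beta1"] = df["se_alpha"]
        df["p_gwis"] = df["p_gwas"]
        r = estimate_overlap_corr(HarmonizedPanel(df))
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_independent_cohorts_give_zero(self):
        panel = simulate_null_sumstat_panel(10_000, 50_000, 20_000,
                                            overlap_corr=0.0, seed=4)
        assert estimate_overlap_corr(panel) == pytest.approx(0.0, abs=0.03)

    def test_overlapping_cohorts_detected_and_ordered(self):
        # conditioning on p > 0.05 in both sources truncates both z's,
        # which attenuates the correlation toward zero; the estimate is
        # a monotone, positively-signed indicator of overlap
        r_low = estimate_overlap_corr(simulate_null_sumstat_panel(
            10_000, 50_000, 20_000, overlap_corr=0.3, seed=5))
        r_high = estimate_overlap_corr(simulate_null_sumstat_panel(
            10_000, 50_000, 20_000, overlap_corr=0.6, seed=5))
        assert r_high > r_low > 0.1
        assert 0.4 < r_high < 0.65

    def test_too_few_null_variants_raises(self):
        panel = simulate_null_sumstat_panel(50, 10_000, 10_000, seed=6)
        with pytest.raises(ValueError, match="p_null_min"):
            estimate_overlap_corr(panel)


def _iv_panel(alpha, beta1, se_alpha=None):
    m = len(alpha)
    return HarmonizedPanel(pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(m)],
        "chrom": "1", "pos": np.arange(m) * 10**6 + 1,
        "alpha_hat": alpha,
        "se_alpha": se_alpha if se_alpha is not None else np.full(m, 0.01),
        "beta1_hat": beta1, "se_beta1": np.full(m, 0.01),
    }))


class TestIvwTheta:
    def test_identity_slope(self):
        panel = _iv_panel([0.1, 0.2, -0.15], [0.1, 0.2, -0.15])
        assert ivw_theta(panel).theta_hat == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        panel = _iv_panel([0.2, 0.1], [0.1, 0.05])
        assert ivw_theta(panel).theta_hat == pytest.approx(2.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        beta1 = rng.normal(0, 0.1, 50)
        alpha = beta1 + rng.normal(0, 0.01, 50)
        t1 = ivw_theta(_iv_panel(alpha, beta1)).theta_hat
        t2 = ivw_theta(_iv_panel(3.0 * alpha, beta1)).theta_hat
        assert t2 == pytest.approx(3.0 * t1, rel=1e-12)

    def test_weighting_matters(self):
        # two discordant instruments; the precise one dominates
        panel = _iv_panel([0.1, 0.4], [0.1, 0.1], se_alpha=[0.001, 0.1])
        assert ivw_theta(panel).theta_hat == pytest.approx(1.0, abs=0.01)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateInstrumentsError):
            ivw_theta(_iv_panel([0.1], [0.1]))
        with pytest.raises(DegenerateInstrumentsError):
            ivw_theta(_iv_panel([0.1, 0.2], [0.0, 0.0]))


class TestTMrGxe:
    def test_hand_computed_statistic(self):
        _, _, stat, _ = t_mr_gxe_arrays(0.10, 0.01, 0.05, 0.01, theta=1.0,
                                        overlap_corr=0.0)
        assert stat == pytest.approx(12.5)

    def test_null_residual_gives_p_one(self, toy_panel):
        df = toy_panel.df.copy()
        df["alpha_hat"] = 2.0 * df["beta1_hat"]
        from mrgxe import CausalEffect
        eff = CausalEffect(theta_hat=2.0, se_theta=0.0, n_iv=5)
        res = screen_panel(HarmonizedPanel(df), eff)
        np.testing.assert_allclose(res["t_mr"], 0.0, atol=1e-20)
        np.testing.assert_allclose(res["p_mr"], 1.0)

    def test_invalid_overlap_correlation_raises(self):
        with pytest.raises(ValueError, match="overlap"):
            t_mr_gxe_arrays(0.1, 0.01, 0.1, 0.01, theta=1.0, overlap_corr=1.0)

    @pytest.mark.parametrize("r", [0.0, 0.5])
    def test_null_calibration_qq_slope(self, r):
        """Under the null with correctly specified overlap, -log10 p follows
        the uniform QQ line with slope within [0.95, 1.05]."""
        panel = simulate_null_sumstat_panel(10_000, 50_000, 20_000,
                                            overlap_corr=r, theta=1.0,
                                            sigma_beta2=0.0, seed=8)
        df = panel.df
        _, _, _, p = t_mr_gxe_arrays(df["alpha_hat"], df["se_alpha"],
                                     df["beta1_hat"], df["se_beta1"],
                                     theta=1.0, overlap_corr=r)
        obs = -np.log10(np.sort(p))
        exp = -np.log10((np.arange(len(p)) + 0.5) / len(p))[::-1]
        exp = np.sort(exp)[::-1]
        obs = np.sort(obs)[::-1]
        slope = np.sum(obs * exp) / np.sum(exp**2)
        assert 0.95 <= slope <= 1.05


class TestImrp:
    def _clean_instruments(self, m=100, seed=9):
        rng = np.random.default_rng(seed)
        beta1 = rng.normal(0, 0.1, m)
        alpha = beta1 + rng.normal(0, 0.01, m)
        return _iv_panel(alpha, beta1)

    def test_no_pleiotropy_is_a_fixed_point(self):
        panel = self._clean_instruments()
        from mrgxe.mr import InstrumentSet
        inst = InstrumentSet(panel, 5e-8, 500_000, 0.1)
        eff = imrp_estimate(inst)
        assert eff.removed_ids == []
        assert eff.n_iterations == 1
        assert eff.theta_hat == pytest.approx(ivw_theta(panel).theta_hat)

    def test_planted_outlier_removed_and_bias_reduced(self):
        panel = self._clean_instruments()
        df = panel.df.copy()
        df.loc[0, "alpha_hat"] = df.loc[0, "beta1_hat"] + 0.2  # pleiotropic
        tainted = HarmonizedPanel(df)
        from mrgxe.mr import InstrumentSet
        inst = InstrumentSet(tainted, 5e-8, 500_000, 0.1)
        eff = imrp_estimate(inst)
        assert "rs0" in eff.removed_ids
        naive = ivw_theta(tainted).theta_hat
        assert abs(eff.theta_hat - 1.0) < abs(naive - 1.0)

    def test_zero_threshold_reproduces_ivw(self):
        panel = self._clean_instruments()
        df = panel.df.copy()
        df.loc[0, "alpha_hat"] += 0.2
        tainted = HarmonizedPanel(df)
        from mrgxe.mr import InstrumentSet
        inst = InstrumentSet(tainted, 5e-8, 500_000, 0.1)
        eff = imrp_estimate(inst, pleio_alpha=0.0)
        assert eff.theta_hat == pytest.approx(ivw_theta(tainted).theta_hat)
        assert eff.removed_ids == []


class TestInteractionEffectMr:
    def test_unit_environment_mean(self, toy_panel):
        from mrgxe import CausalEffect
        v = next(toy_panel.variants())  # alpha 0.20, beta1 0.10
        eff = CausalEffect(theta_hat=1.5, se_theta=0.0, n_iv=5)
        est, se = interaction_effect_mr(v, eff, mu_E=1.0)
        assert est == pytest.approx(0.05)
        est2, _ = interaction_effect_mr(v, eff, mu_E=2.0)
        assert est2 == pytest.approx(0.025)

    def test_zero_mean_not_identifiable(self, toy_panel):
        from mrgxe import CausalEffect
        v = next(toy_panel.variants())
        with pytest.raises(ValueError):
            interaction_effect_mr(v, CausalEffect(1.0, 0.0, 5), mu_E=0.0)


class TestExpectedTheta:
    def test_degenerate_zero(self):
        assert expected_theta(0.0, 1e4, 1e4, 0, 1, 1, 1, 1) == 0.0

    def test_full_overlap_identical_moments_is_one(self):
        assert expected_theta(0.01, 2e4, 2e4, 2e4, 1.5, 1.0, 1.5, 1.0) == \
            pytest.approx(1.0)

    def test_bounded_by_one_under_valid_overlap(self):
        for n0 in (0, 5_000, 20_000):
            val = expected_theta(0.001, 2e4, 2e4, n0, 1, 1, 1, 1)
            assert val <= 1.0 + 1e-12

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            expected_theta(0.01, 1e4, 1e4, 2e4, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            expected_theta(-0.01, 1e4, 1e4, 0, 1, 1, 1, 1)
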