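import numpy as np
import pytest

from targetmr.exceptions import MethodUnavailableError, UndefinedRatioError
from targetmr.mr import (cochran_q, egger, ivw, mr_lasso, primary_estimate,
                         steiger, wald_ratio, weighted_median, weighted_mode)
from targetmr.simulate import SimConfig, simulate_two_sample

from conftest import harmonized_from_sim, make_harmonized


class TestWald:
    def test_direct_ratio(self):
        res = wald_ratio({"beta_x": 0.10, "beta_y": 0.05, "se_y": 0.01})
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)
        assert res.ci_low == pytest.approx(0.5 - 1.96 * 0.1, abs=1e-4)

    def test_zero_outcome_effect(self):
        assert wald_ratio({"beta_x": 0.1, "beta_y": 0.0, "se_y": 0.01}).beta == 0.0

    def test_sign_propagates(self):
        res = wald_ratio({"beta_x": -0.10, "beta_y": 0.05, "se_y": 0.01})
        assert res.beta == pytest.approx(-0.5)

    def test_zero_exposure_effect_undefined(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio({"beta_x": 0.0, "beta_y": 0.05, "se_y": 0.01})


class TestIVW:
    def test_consensus_of_identical_ratios(self):
        ht = make_harmonized([0.1, 0.2], [0.05, 0.10], [0.01, 0.01])
        assert ivw(ht, "fixed").beta == pytest.approx(0.5)

    def test_hand_computed_weighted_average(self):
        # ratio weights (100, 400): theta = (100*0.5 + 400*1.0)/500 = 0.9
        ht = make_harmonized([0.1, 0.2], [0.05, 0.2], [0.01, 0.01])
        res = ivw(ht, "fixed")
        assert res.beta == pytest.approx(0.9)
        # independent check: weighted least squares through the origin
        bx, by, w = np.array([0.1, 0.2]), np.array([0.05, 0.2]), 1e4
        sol, *_ = np.linalg.lstsq((np.sqrt(w) * bx)[:, None],
                                  np.sqrt(w) * by, rcond=None)
        assert res.beta == pytest.approx(float(sol[0]))
        assert res.se == pytest.approx((0.1**2 * 1e4 + 0.2**2 * 1e4) ** -0.5)

    def test_random_effects_inflate_se_only_when_q_exceeds_df(self):
        ht = make_harmonized([0.1, 0.2, 0.1, 0.2], [0.05, 0.1, 0.05, 0.1],
                             [0.01] * 4)
        fixed = ivw(ht, "fixed")
        random = ivw(ht, "random_multiplicative")
        assert random.se == fixed.se  # Q = 0 here, multiplier clamps at 1
        noisy = make_harmonized([0.1, 0.2, 0.1, 0.2], [0.09, 0.1, 0.02, 0.3],
                                [0.01] * 4)
        assert ivw(noisy, "random_multiplicative").se > ivw(noisy, "fixed").se

    def test_single_snp_directs_to_wald(self):
        with pytest.raises(MethodUnavailableError, match="wald"):
            ivw(make_harmonized([0.1], [0.05], [0.01]))

    def test_invariant_to_order_and_joint_sign_flip(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.2, 8)
        by = 0.4 * bx + rng.normal(0, 0.01, 8)
        sy = rng.uniform(0.005, 0.02, 8)
        base = ivw(make_harmonized(bx, by, sy), "fixed").beta
        perm = rng.permutation(8)
        assert ivw(make_harmonized(bx[perm], by[perm], sy[perm]),
                   "fixed").beta == pytest.approx(base)
        flip = np.where(rng.random(8) < 0.5, -1.0, 1.0)
        assert ivw(make_harmonized(flip * bx, flip * by, sy),
                   "fixed").beta == pytest.approx(base)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3])
        ht = make_harmonized(bx, 0.1 + 0.5 * bx, [0.01] * 3)
        slope, intercept = egger(ht)
        assert slope.beta == pytest.approx(0.5)
        assert intercept.beta == pytest.approx(0.1)

    def test_all_zero_outcomes(self):
        ht = make_harmonized([0.1, 0.2, 0.3], [0.0] * 3, [0.01] * 3)
        slope, intercept = egger(ht)
        assert slope.beta == pytest.approx(0.0, abs=1e-12)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_snps(self):
        with pytest.raises(MethodUnavailableError):
            egger(make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_balanced_pleiotropy_gives_null_intercept_on_average(self):
        # InSIDE holds, pleiotropy centred on zero: E[intercept] = 0
        rng = np.random.default_rng(42)
        k, reps = 10, 500
        intercepts = np.empty(reps)
        for i in range(reps):
            bx = rng.uniform(0.05, 0.2, k)
            alpha = rng.normal(0.0, 0.02, k)
            sy = np.full(k, 0.01)
            by = 0.3 * bx + alpha + rng.normal(0, sy)
            intercepts[i] = egger(make_harmonized(bx, by, sy))[1].beta
        sem = intercepts.std(ddof=1) / np.sqrt(reps)
        assert abs(intercepts.mean()) < 4 * sem


class TestWeightedMedian:
    def test_cumulative_midpoint_interpolation(self):
        # equal weights, ratios (1, 2, 3): midpoints (1/6, 1/2, 5/6) -> 2
        ht = make_harmonized([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert weighted_median(ht, boot_reps=50, seed=0).beta == pytest.approx(2.0)

    def test_majority_valid_weight_recovers_truth(self):
        bx = np.full(10, 0.1)
        by = 0.3 * bx
        by[:4] += 5.0  # four grossly invalid instruments, <50% of weight
        ht = make_harmonized(bx, by, np.full(10, 0.01))
        assert weighted_median(ht, boot_reps=50, seed=0).beta == pytest.approx(0.3)

    def test_bootstrap_se_deterministic_under_seed(self):
        ht = make_harmonized([0.1, 0.15, 0.2], [0.05, 0.08, 0.1],
                             [0.01, 0.01, 0.01])
        a = weighted_median(ht, boot_reps=200, seed=7)
        b = weighted_median(ht, boot_reps=200, seed=7)
        assert a.se == b.se and a.se > 0


class TestWeightedMode:
    def test_degenerate_cluster_returns_common_ratio(self):
        ht = make_harmonized([0.1, 0.2, 0.3],
                             [0.07, 0.14, 0.21], [0.01] * 3)
        assert weighted_mode(ht, boot_reps=50, seed=0).beta == pytest.approx(0.7)

    def test_plurality_valid_cluster_wins(self):
        rng = np.random.default_rng(3)
        bx = np.full(10, 0.1)
        ratios = np.concatenate([0.3 + rng.normal(0, 0.01, 7),
                                 2.0 + rng.normal(0, 0.01, 3)])
        ht = make_harmonized(bx, ratios * bx, np.full(10, 0.01))
        res = weighted_mode(ht, boot_reps=50, seed=0)
        assert abs(res.beta - 0.3) < 0.1

    def test_bandwidth_sensitivity_is_smooth(self):
        rng = np.random.default_rng(5)
        bx = np.full(10, 0.1)
        ratios = 0.3 + rng.normal(0, 0.02, 10)
        ht = make_harmonized(bx, ratios * bx, np.full(10, 0.01))
        narrow = weighted_mode(ht, bandwidth_factor=1.0, boot_reps=50, seed=0)
        wide = weighted_mode(ht, bandwidth_factor=2.0, boot_reps=50, seed=0)
        assert abs(narrow.beta - wide.beta) < 0.05
        assert wide.notes["bandwidth_factor"] == 2.0


class TestMRLasso:
    def test_all_valid_equals_ivw_with_full_retention(self):
        bx = np.linspace(0.05, 0.2, 6)
        ht = make_harmonized(bx, 0.4 * bx, np.full(6, 0.01))
        res = mr_lasso(ht)
        assert res.beta == pytest.approx(ivw(ht, "fixed").beta)
        assert res.notes["n_valid"] == 6

    def test_gross_outlier_excluded(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.05, 0.2, 10)
        sy = np.full(10, 0.01)
        by = 0.4 * bx + rng.normal(0, sy)
        by[3] += 0.5  # gross pleiotropic outlier
        ht = make_harmonized(bx, by, sy)
        res = mr_lasso(ht)
        assert "rs3" in res.notes["excluded"]
        keep = np.ones(10, bool)
        keep[3] = False
        expected = ivw(make_harmonized(bx[keep], by[keep], sy[keep]), "fixed")
        assert res.beta == pytest.approx(expected.beta, rel=1e-6)

    def test_requires_three_snps(self):
        with pytest.raises(MethodUnavailableError):
            mr_lasso(make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


class TestDiagnostics:
    def test_q_zero_for_identical_ratios(self):
        ht = make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        res = cochran_q(ht)
        assert res.Q == pytest.approx(0.0, abs=1e-20)
        assert res.pval == pytest.approx(1.0)

    def test_q_hand_computed(self):
        # ratios (0.5, 1.0), weights (100, 400), IVW 0.9:
        # Q = 100*0.16 + 400*0.01 = 20
        ht = make_harmonized([0.1, 0.2], [0.05, 0.2], [0.01, 0.01])
        res = cochran_q(ht)
        assert res.Q == pytest.approx(20.0)
        assert res.df == 1

    def test_steiger_obvious_direction(self):
        ht = make_harmonized([0.1, 0.1], [0.001, 0.001], [0.05, 0.05],
                             se_x=[0.01, 0.01], n_x=10000.0, n_y=10000.0)
        res = steiger(ht)
        assert res.direction_correct
        assert res.r2_exposure > res.r2_outcome

    def test_steiger_equal_r2_is_boundary(self):
        ht = make_harmonized([0.1], [0.1], [0.02], se_x=[0.02],
                             n_x=10000.0, n_y=10000.0)
        res = steiger(ht)
        assert not res.direction_correct
        assert res.pval == pytest.approx(1.0, abs=1e-9)


class TestNoiseFreeEquivalence:
    def test_all_estimators_recover_theta_without_noise(self):
        cfg = SimConfig(n_snp=12, ld_block_size=1, ld_rho=0.0, n_causal=12,
                        theta=0.5, noise_scale_exposure=0.0,
                        noise_scale_outcome=0.0, seed=21)
        x, y, ld, truth = simulate_two_sample(cfg)
        ht = harmonized_from_sim(x, y)
        assert ivw(ht).beta == pytest.approx(0.5, abs=1e-12)
        slope, intercept = egger(ht)
        assert slope.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept.beta == pytest.approx(0.0, abs=1e-10)
        assert weighted_median(ht, boot_reps=20, seed=0).beta == pytest.approx(
            0.5, abs=1e-12)
        assert weighted_mode(ht, boot_reps=20, seed=0).beta == pytest.approx(
            0.5, abs=1e-12)
        assert mr_lasso(ht).beta == pytest.approx(0.5, abs=1e-12)

    def test_primary_estimate_dispatches_on_snp_count(self):
        one = make_harmonized([0.1], [0.05], [0.01])
        assert primary_estimate(one).method == "wald"
        two = make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        assert primary_estimate(two).method.startswith("ivw")
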