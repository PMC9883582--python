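import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from twosmr.estimators import (
    ivw,
    mr_egger,
    mvmr_ivw,
    to_odds_scale,
    wald_ratio,
    wald_ratios,
    weighted_median,
)
from twosmr.exceptions import CollinearityError, ValidationError
from twosmr.harmonization import HarmonizedPair

from conftest import make_set


class TestWaldRatio:
    def test_definition_and_sign(self):
        p = HarmonizedPair("rs1", 0.02, 0.003, 0.004, 0.01, 0.3, 0.3)
        est = wald_ratio(p)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.5)
        n = HarmonizedPair("rs1", -0.02, 0.003, 0.004, 0.01, 0.3, 0.3)
        assert wald_ratio(n).beta == pytest.approx(-0.2)

    def test_second_order_se_exceeds_first(self):
        p = HarmonizedPair("rs1", 0.02, 0.01, 0.01, 0.01, 0.3, 0.3)
        assert wald_ratio(p, se_mode="delta2").se > wald_ratio(p, se_mode="delta1").se

    def test_degenerate_instrument(self):
        with pytest.raises(ValidationError):
            wald_ratio(HarmonizedPair("rs1", 0.0, 0.003, 0.004, 0.01, 0.3, 0.3))

    def test_three_snp_hand_computation(self):
        hset = make_set([0.02, -0.04, 0.05], [0.004, 0.002, -0.01], [0.01, 0.02, 0.005])
        theta, se = wald_ratios(hset)
        np.testing.assert_allclose(theta, [0.2, -0.05, -0.2])
        np.testing.assert_allclose(se, [0.5, 0.5, 0.1])


class TestIVW:
    def test_fixed_equals_brute_force_inverse_variance_mean(self, random_set_factory):
        for seed in range(5):
            hset = random_set_factory(seed)
            est, het = ivw(hset, mode="fixed")
            # oracle: explicit loop over ratios
            num = den = 0.0
            for p in hset.pairs:
                theta = p.beta_out / p.beta_exp
                w = (abs(p.beta_exp) / p.se_out) ** 2
                num += w * theta
                den += w
            assert est.beta == pytest.approx(num / den, abs=1e-12)
            assert est.se == pytest.approx(den**-0.5, abs=1e-12)

    def test_equals_wls_through_origin(self, toy_set):
        est, _ = ivw(toy_set, mode="fixed")
        res = sm.WLS(
            toy_set.beta_out, toy_set.beta_exp[:, None], weights=1.0 / toy_set.se_out**2
        ).fit()
        assert est.beta == pytest.approx(res.params[0], abs=1e-12)

    def test_homogeneous_limit(self):
        hset = make_set([0.02, 0.04, 0.05], [0.002, 0.004, 0.005], [0.01, 0.02, 0.025])
        est, het = ivw(hset)
        assert est.beta == pytest.approx(0.1)
        assert het.q_stat == pytest.approx(0.0, abs=1e-20)
        assert het.pvalue == pytest.approx(1.0)

    def test_random_p_never_below_fixed(self, random_set_factory):
        for seed in range(5):
            hset = random_set_factory(seed)
            est_r, het = ivw(hset, mode="random")
            est_f, _ = ivw(hset, mode="fixed")
            if het.q_stat / het.df > 1:
                assert est_r.pvalue >= est_f.pvalue
                assert est_r.se > est_f.se
            else:
                assert est_r.pvalue == pytest.approx(est_f.pvalue)
            assert est_r.beta == est_f.beta

    def test_single_pair_degenerates_to_wald(self):
        hset = make_set([0.02], [0.004], [0.01])
        with pytest.warns(UserWarning, match="single instrument"):
            est, het = ivw(hset)
        assert est.beta == pytest.approx(0.2)
        assert het.df == 0

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            ivw(make_set([], [], []))


class TestWeightedMedian:
    def test_equal_weight_odd_count_is_middle_ratio(self):
        hset = make_set([0.1, 0.1, 0.1], [0.01, 0.02, 0.09], [0.01, 0.01, 0.01])
        est = weighted_median(hset, reps=100, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_permutation_invariance(self, random_set_factory):
        hset = random_set_factory(3)
        perm = np.random.default_rng(0).permutation(len(hset.pairs))
        shuffled = type(hset)([hset.pairs[i] for i in perm])
        a = weighted_median(hset, reps=100, seed=1)
        b = weighted_median(shuffled, reps=100, seed=1)
        assert a.beta == pytest.approx(b.beta, abs=1e-15)

    def test_equal_weight_duplication_invariance(self):
        # splitting every equally-weighted point into two half-weight copies
        # leaves the interpolated median unchanged
        ratios = [0.0, 0.1, 0.25, 0.9]
        x = np.full(4, 0.1)
        hset = make_set(x, np.array(ratios) * x, np.full(4, 0.02))
        dup = make_set(
            np.tile(x, 2),
            np.tile(np.array(ratios) * x, 2),
            np.full(8, 0.02 * math.sqrt(2)),  # doubled variance = halved weight
        )
        a = weighted_median(hset, reps=100, seed=0)
        b = weighted_median(dup, reps=100, seed=0)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)

    def test_weight_concentration_limit(self):
        # nearly all weight on one SNP pulls the median to its ratio
        hset = make_set(
            [0.05, 0.05, 0.05], [0.05 * 0.5, 0.05 * 0.1, 0.05 * 0.9],
            [1e-6, 0.05, 0.05],
        )
        est = weighted_median(hset, reps=100, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-3)

    def test_bootstrap_seeded_and_warns_on_few_reps(self, random_set_factory):
        hset = random_set_factory(1)
        a = weighted_median(hset, reps=200, seed=5)
        b = weighted_median(hset, reps=200, seed=5)
        assert a.se == b.se
        with pytest.warns(UserWarning, match="reps"):
            weighted_median(hset, reps=50, seed=5)

    def test_needs_three_instruments(self):
        with pytest.raises(ValidationError):
            weighted_median(make_set([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))


class TestMREgger:
    def test_exact_fit_recovers_intercept_and_slope(self):
        x = np.array([0.02, 0.03, 0.04, 0.05])
        y = 0.01 + 0.3 * x
        hset = make_set(x, y, np.full(4, 0.01))
        slope, intercept = mr_egger(hset)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert intercept.beta == pytest.approx(0.01, abs=1e-12)

    def test_orientation_invariance(self):
        # flipping the reported allele of some SNPs (negating both betas)
        # cannot change the Egger fit
        x = np.array([0.02, -0.03, 0.04, -0.05, 0.025])
        y = np.sign(x) * (0.005 + 0.2 * np.abs(x))
        hset = make_set(x, y, np.full(5, 0.01))
        slope, intercept = mr_egger(hset)
        assert slope.beta == pytest.approx(0.2, abs=1e-12)
        assert intercept.beta == pytest.approx(0.005, abs=1e-12)

    def test_matches_statsmodels_wls(self, random_set_factory):
        hset = random_set_factory(11)
        x = np.abs(hset.beta_exp)
        y = hset.beta_out * np.sign(hset.beta_exp)
        res = sm.WLS(y, sm.add_constant(x), weights=1.0 / hset.se_out**2).fit()
        slope, intercept = mr_egger(hset)
        assert slope.beta == pytest.approx(res.params[1], abs=1e-12)
        assert intercept.beta == pytest.approx(res.params[0], abs=1e-12)
        # SE: statsmodels sigma-scaled SE times our floor-at-1 convention
        sigma = math.sqrt(res.scale)
        assert slope.se == pytest.approx(res.bse[1] * max(1, sigma) / sigma, rel=1e-10)

    def test_zero_intercept_refit_equals_ivw(self, random_set_factory):
        hset = random_set_factory(4)
        x = np.abs(hset.beta_exp)
        y = hset.beta_out * np.sign(hset.beta_exp)
        res = sm.WLS(y, x[:, None], weights=1.0 / hset.se_out**2).fit()
        est_f, _ = ivw(hset, mode="fixed")
        assert res.params[0] == pytest.approx(est_f.beta, abs=1e-12)

    def test_needs_three_instruments(self):
        with pytest.raises(ValidationError):
            mr_egger(make_set([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))


class TestMVMR:
    def test_single_exposure_reduces_to_fixed_ivw(self, random_set_factory):
        hset = random_set_factory(8)
        est_f, _ = ivw(hset, mode="fixed")
        (mv,) = mvmr_ivw(hset.beta_exp[:, None], hset.beta_out, hset.se_out)
        assert mv.beta == pytest.approx(est_f.beta, abs=1e-12)

    def test_two_exposure_recovery(self):
        """Known direct effects (0.3, -0.1) recovered within 2 MC-SEs."""
        rng = np.random.default_rng(42)
        J, reps = 500, 40
        means = []
        for _ in range(reps):
            g1 = rng.uniform(0.02, 0.05, J) * rng.choice([-1, 1], J)
            g2 = 0.3 * g1 + rng.uniform(0.01, 0.04, J) * rng.choice([-1, 1], J)
            sy = np.full(J, 0.004)
            y = 0.3 * g1 - 0.1 * g2 + rng.normal(0, sy)
            ests = mvmr_ivw(np.column_stack([g1, g2]), y, sy)
            means.append([ests[0].beta, ests[1].beta])
        means = np.array(means)
        for k, truth in enumerate((0.3, -0.1)):
            mcse = means[:, k].std(ddof=1) / math.sqrt(reps)
            assert abs(means[:, k].mean() - truth) < 2 * mcse + 1e-4

    def test_duplicate_column_collinearity_error(self):
        x = np.linspace(0.01, 0.05, 10)
        X = np.column_stack([x, x])
        import pandas as pd

        with pytest.raises(CollinearityError) as exc:
            mvmr_ivw(pd.DataFrame(X, columns=["mdd", "mdd_copy"]), 0.1 * x, np.full(10, 0.01))
        assert set(exc.value.columns) & {"mdd", "mdd_copy"}

    def test_more_exposures_than_snps_rejected(self):
        with pytest.raises(ValidationError):
            mvmr_ivw(np.ones((2, 3)), [0.1, 0.2], [0.01, 0.01])


class TestOddsScale:
    def test_null_beta_gives_unit_or(self, random_set_factory):
        est, _ = ivw(make_set([0.02, 0.04, 0.05], [0.0, 0.0, 0.0], [0.01, 0.02, 0.025]))
        assert to_odds_scale(est).or_ == pytest.approx(1.0)

    def test_ci_arithmetic_consistency(self):
        # beta 0.0834, se 0.0373 -> OR 1.087 with CI about (1.011, 1.170)
        from twosmr.estimators import _estimate

        est = _estimate("ivw", 0.0834, 0.0373, 92)
        assert est.or_ == pytest.approx(1.087, abs=5e-4)
        assert est.or_ci_low == pytest.approx(1.011, abs=2e-3)
        assert est.or_ci_high == pytest.approx(1.170, abs=2e-3)

    def test_negation_symmetry(self):
        from twosmr.estimators import _estimate

        a = to_odds_scale(_estimate("wald", 0.25, 0.1, 1))
        b = to_odds_scale(_estimate("wald", -0.25, 0.1, 1))
        assert a.or_ == pytest.approx(1 / b.or_)
        assert a.or_ci_high == pytest.approx(1 / b.or_ci_low)

    @settings(max_examples=30, deadline=None)
    @given(beta=st.floats(-2, 2), se=st.floats(1e-3, 1.0))
    def test_or_is_exp_beta_and_ci_brackets(self, beta, se):
        from twosmr.estimators import _estimate

        est = _estimate("ivw", beta, se, 10)
        assert est.or_ == pytest.approx(math.exp(est.beta))
        assert est.ci_low <= est.beta <= est.ci_high
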