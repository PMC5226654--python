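import numpy as np
import pytest
from scipy import stats as sps

from spikecad.counting import joint_count, layer_totals
from spikecad.stats import (SegmentScheme, difference_count,
                            hypergeometric_moments, pair_test,
                            segmented_variance, uncorrected_statistic,
                            uncorrected_test)
from spikecad.stats import _layer_cov_cross_lag, _layer_var


def permuted_joint_counts(cA, cB, lags, n_perm, seed):
    """Joint counts at each lag under random permutation of B's bins."""
    rng = np.random.default_rng(seed)
    T = cA.size
    out = {l: np.empty(n_perm) for l in lags}
    for i in range(n_perm):
        b = rng.permutation(cB)
        for l in lags:
            out[l][i] = joint_count(cA, b, l)
    return out


class TestHypergeometricMoments:
    def test_binary_closed_form(self):
        # 3 and 4 ones in 10 bins: mean 1.2, hypergeometric variance 0.56
        cA = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        cB = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        m = hypergeometric_moments(cA, cB, 0)
        assert m.mean == pytest.approx(1.2)
        assert m.variance == pytest.approx(0.56)

    def test_silent_unit_zero_moments(self):
        m = hypergeometric_moments(np.zeros(10, dtype=int),
                                   np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0]), 0)
        assert m.mean == 0.0 and m.variance == 0.0

    def test_two_layer_toy_against_permutation_oracle(self):
        # layer totals A=(2,1), B=(3,1) in 10 bins: mean (2*3 + 1*1)/10
        cA = np.array([2, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        cB = np.array([2, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        m = hypergeometric_moments(cA, cB, 0)
        assert m.mean == pytest.approx(0.7)
        perms = permuted_joint_counts(cA, cB, [0], 100_000, seed=1)[0]
        assert perms.mean() == pytest.approx(m.mean, rel=0.02)
        assert perms.var(ddof=1) == pytest.approx(m.variance, rel=0.03)

    def test_reduces_to_textbook_hypergeometric_when_binary(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            N = int(rng.integers(10, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            var = _layer_var(np.array([K]), np.array([n]), N)
            assert var == pytest.approx(sps.hypergeom(N, K, n).var(), rel=1e-9)

    def test_window_marginals_used_at_nonzero_lag(self):
        cA = np.array([3, 0, 1, 0, 1, 0])
        cB = np.array([0, 1, 0, 1, 0, 2])
        m = hypergeometric_moments(cA, cB, 2)
        assert m.effective_length == 4
        nA = layer_totals(cA[:4])
        nB = layer_totals(cB[2:])
        assert m.mean == pytest.approx(sum(int(a) * int(b) for a, b in
                                           zip(nA, nB)) / 4)


class TestCrossLagCovariance:
    def test_small_negative_relative_to_variance(self):
        # forward and reference counts are weakly anti-correlated under the
        # null: the model term is negative and O(1/(n-1)) of the variance
        rng = np.random.default_rng(3)
        for _ in range(20):
            cA = rng.binomial(50, 0.04, 400)
            cB = rng.binomial(50, 0.06, 400)
            nA, nB = layer_totals(cA), layer_totals(cB)
            var = _layer_var(nA, nB, cA.size)
            cov = _layer_cov_cross_lag(nA, nB, cA.size)
            assert cov == pytest.approx(-var / (cA.size - 1))

    def test_difference_variance_matches_permutation_multicount(self):
        # the combined estimator 2 var - 2 cov tracks the permutation
        # variance of the difference count for multi-valued counts too
        rng = np.random.default_rng(30)
        cA = rng.binomial(100, 0.01, 1000)
        cB = rng.binomial(100, 0.03, 1000)
        perms = permuted_joint_counts(cA, cB, [5, -5], 20_000, seed=31)
        emp = (perms[5] - perms[-5]).var(ddof=1)
        s2 = segmented_variance(cA, cB, 5, -5, SegmentScheme(100))
        assert s2 == pytest.approx(emp, rel=0.08)


class TestUncorrectedStatistic:
    def test_zero_when_count_matches_null_mean(self):
        # identical marginals, observed == expected by construction
        cA = np.array([1, 0] * 10)
        cB = np.array([1, 0] * 10)
        m = hypergeometric_moments(cA, cB, 1)
        s = uncorrected_statistic(cA, cB, 1)
        assert s == pytest.approx((joint_count(cA, cB, 1) - m.mean)
                                  / np.sqrt(m.variance))

    def test_arithmetic_from_verified_moments(self):
        cA = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        cB = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        s = uncorrected_statistic(cA, cB, 0)
        assert s == pytest.approx((joint_count(cA, cB, 0) - 1.2) / np.sqrt(0.56))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            uncorrected_statistic(np.ones(10, int), np.ones(10, int), 0)

    def test_t_distributed_under_stationarity(self):
        # multi-count stationary pairs: S follows t with 2(T-l)M - 1 dof
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(800):
            cA = rng.binomial(100, 0.02, 400)
            cB = rng.binomial(100, 0.03, 400)
            s, dof, _ = uncorrected_test(cA, cB, 2)
            pvals.append(sps.t.cdf(s, dof))
        d = sps.kstest(pvals, "uniform")
        assert d.pvalue > 0.01


class TestDifferenceCount:
    def test_direct_subtraction(self):
        rng = np.random.default_rng(6)
        cA = rng.poisson(0.5, 100)
        cB = rng.poisson(0.5, 100)
        assert difference_count(cA, cB, 1, -1) == \
            joint_count(cA, cB, 1) - joint_count(cA, cB, -1)

    def test_synchrony_reference_form(self):
        cA = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        cB = np.array([1, 0, 1, 0, 0, 0, 1, 0])
        assert difference_count(cA, cB, 0, -2) == \
            joint_count(cA, cB, 0) - joint_count(cA, cB, -2)

    def test_symmetric_counts_cancel(self):
        c = np.array([1, 0, 0, 1, 0, 0, 1, 0, 0])
        assert difference_count(c, c, 2, -2) == 0

    def test_equal_lags_rejected(self):
        with pytest.raises(ValueError):
            difference_count(np.ones(5, int), np.ones(5, int), 1, 1)


class TestSegmentedVariance:
    def test_single_segment_matches_global_identity(self):
        rng = np.random.default_rng(7)
        cA = rng.binomial(20, 0.1, 80)
        cB = rng.binomial(20, 0.15, 80)
        s2 = segmented_variance(cA, cB, 2, -2, SegmentScheme(200))
        nA, nB = layer_totals(cA), layer_totals(cB)
        expect = 2 * _layer_var(nA, nB, 80) - 2 * _layer_cov_cross_lag(nA, nB, 80)
        assert s2 == pytest.approx(expect)

    def test_matches_permutation_variance_of_difference(self):
        # stationary binary pair, k=100, C=10
        rng = np.random.default_rng(8)
        cA = (rng.random(1000) < 0.08).astype(np.int64)
        cB = (rng.random(1000) < 0.08).astype(np.int64)
        l = 3
        perms = permuted_joint_counts(cA, cB, [l, -l], 10_000, seed=9)
        emp = (perms[l] - perms[-l]).var(ddof=1)
        s2 = segmented_variance(cA, cB, l, -l, SegmentScheme(100))
        assert s2 == pytest.approx(emp, rel=0.08)

    def test_silent_segment_contributes_nothing(self):
        cA = np.concatenate([np.zeros(100, int), np.ones(100, int)])
        cB = np.concatenate([np.zeros(100, int),
                             (np.arange(100) % 3 == 0).astype(np.int64)])
        s2_full = segmented_variance(cA, cB, 1, -1, SegmentScheme(100))
        s2_tail = segmented_variance(cA[100:], cB[100:], 1, -1,
                                     SegmentScheme(100))
        assert s2_full == pytest.approx(s2_tail)

    def test_degenerate_segments_rejected(self):
        with pytest.raises(ValueError):
            segmented_variance(np.ones(10, int), np.ones(10, int), 1, -1,
                               SegmentScheme(1))
        with pytest.raises(ValueError):
            SegmentScheme(3).bounds(100, lag=5)


class TestPairTest:
    def test_delayed_copy_detected(self):
        rng = np.random.default_rng(10)
        base = (rng.random(2000) < 0.2).astype(np.int64)
        cB = np.roll(base, 1) + (rng.random(2000) < 0.02)
        res = pair_test(base, cB.astype(np.int64), l_max=5,
                        corrected_alpha=1e-6)
        assert res.selected_lag == 1
        assert res.significant and res.p_value < 1e-6

    def test_sparse_pair_gated_out(self):
        # expected joint count below 4 -> untested, never significant
        cA = np.zeros(500, dtype=np.int64)
        cB = np.zeros(500, dtype=np.int64)
        cA[[10, 50, 90]] = 1
        cB[[11, 51, 91]] = 1
        res = pair_test(cA, cB, l_max=3)
        assert res.selected_lag == 1 and res.difference > 0
        assert not res.gate_passed and not res.significant

    def test_zero_variance_flagged_untestable(self):
        cA = np.ones(300, dtype=np.int64)   # constant after floor: silent
        cB = np.ones(300, dtype=np.int64)
        res = pair_test(cA, cB, l_max=2)
        assert not res.testable and not res.significant

    def test_difference_nonnegative_with_argmax_selection(self):
        rng = np.random.default_rng(11)
        for seed in range(20):
            r = np.random.default_rng(seed)
            cA = r.binomial(30, 0.05, 600)
            cB = r.binomial(30, 0.05, 600)
            res = pair_test(cA, cB, l_max=4)
            assert res.difference >= 0

    def test_null_mean_of_difference_near_zero(self):
        # E[#ABBA] = 0 under independence: sample mean within 3 SE
        rng = np.random.default_rng(12)
        ds = [difference_count(rng.binomial(1, 0.05, 1000),
                               rng.binomial(1, 0.05, 1000), 2, -2)
              for _ in range(600)]
        ds = np.asarray(ds, dtype=float)
        assert abs(ds.mean()) <= 3 * ds.std(ddof=1) / np.sqrt(ds.size)

    def test_fixed_reference_policy(self):
        rng = np.random.default_rng(13)
        cA = rng.binomial(20, 0.1, 500)
        cB = rng.binomial(20, 0.1, 500)
        res = pair_test(cA, cB, l_max=4, reference_policy="fixed")
        assert res.reference_lag in (-5, 5)
        assert abs(res.reference_lag) == 5

    def test_conservative_dof_for_short_series(self):
        rng = np.random.default_rng(14)
        cA = rng.binomial(40, 0.3, 40)
        cB = rng.binomial(40, 0.3, 40)
        res = pair_test(cA, cB, l_max=2, dof_policy="auto",
                        scheme=SegmentScheme(20))
        assert res.dof == 40 - abs(res.selected_lag)
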