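"""Univariate tests, correlations, and the undetected-diversity estimator."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from nirpipe import stats


class TestTTest:
    def test_identical_groups(self):
        res = stats.t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_chlorophyll_summary_entry(self):
        # biomass proxy means/SDs entered from a printed table (n = 3 each)
        hbm = stats.GroupSummary("HBM", 3, 28.61, 1.61)
        lbm = stats.GroupSummary("LBM", 3, 13.26, 3.48)
        res = stats.t_test(hbm, lbm, mode="pooled")
        assert res.statistic == pytest.approx(6.93, abs=0.01)
        assert res.df == 4
        assert res.p_value < 0.05

    def test_doubling_sds_halves_t(self):
        a = stats.GroupSummary("A", 5, 10.0, 2.0)
        b = stats.GroupSummary("B", 5, 8.0, 3.0)
        a2 = stats.GroupSummary("A", 5, 10.0, 4.0)
        b2 = stats.GroupSummary("B", 5, 8.0, 6.0)
        t1 = stats.t_test(a, b).statistic
        t2 = stats.t_test(a2, b2).statistic
        assert t2 == pytest.approx(t1 / 2)

    def test_raw_values_equal_their_summary(self, rng):
        a = rng.normal(5, 2, size=8)
        b = rng.normal(6, 2, size=10)
        r1 = stats.t_test(a, b)
        r2 = stats.t_test(
            stats.GroupSummary.from_values("A", a),
            stats.GroupSummary.from_values("B", b),
        )
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_welch_df_below_pooled_for_unequal_variances(self):
        a = stats.GroupSummary("A", 10, 0.0, 1.0)
        b = stats.GroupSummary("B", 10, 1.0, 5.0)
        assert stats.t_test(a, b, mode="welch").df < stats.t_test(a, b).df

    def test_zero_variance_equal_means(self):
        res = stats.t_test([2.0, 2.0], [2.0, 2.0])
        assert (res.statistic, res.p_value) == (0.0, 1.0)


class TestLevene:
    def test_identical_spread_high_p(self):
        res = stats.levene([1, 2, 3, 4], [11, 12, 13, 14])
        assert res.p_value > 0.9

    def test_detects_hundredfold_variance(self):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, size=20)
            b = rng.normal(0, 10, size=20)
            assert stats.levene(a, b).p_value < 0.01

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            stats.levene([1.0], [2.0, 3.0])

    def test_all_identical_values(self):
        res = stats.levene([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (res.statistic, res.p_value) == (0.0, 1.0)


def enumeration_oracle(a, b):
    """Independent exact two-sided Mann-Whitney p: enumerate group splits."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    na = len(a)
    # midranks computed from scratch
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    mu = na * (n - na) / 2.0
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n), na):
        u = ranks[list(comb)].sum() - na * (na + 1) / 2.0
        total += 1
        hits += abs(u - mu) >= dev - 1e-12
    return u_obs, hits / total


class TestMannWhitney:
    def test_identical_samples_central_u(self):
        res = stats.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)

    def test_fully_separated_triplets(self):
        res = stats.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic in (0.0, 9.0)
        assert res.p_value == pytest.approx(0.1)

    def test_all_ties_p_one(self):
        res = stats.mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_oracle_all_small_sizes(self, rng):
        for na in range(3, 6):
            for nb in range(3, 6):
                a = rng.integers(0, 6, size=na).astype(float)  # ties likely
                b = rng.integers(0, 6, size=nb).astype(float)
                res = stats.mann_whitney_u(a, b)
                u, p = enumeration_oracle(a, b)
                assert res.statistic == pytest.approx(u)
                assert res.p_value == pytest.approx(p)

    def test_agrees_with_scipy_exact_when_tie_free(self, rng):
        a = rng.normal(0, 1, size=6)
        b = rng.normal(1, 1, size=7)
        res = stats.mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_u([], [1.0])


class TestTypeIError:
    def test_t_and_mwu_hold_their_level_under_the_null(self):
        rng = np.random.default_rng(123)
        n_rep = 2000
        a = rng.normal(0, 1, size=(n_rep, 12))
        b = rng.normal(0, 1, size=(n_rep, 12))
        t_hits = sum(
            stats.t_test(a[i], b[i]).p_value < 0.05 for i in range(n_rep)
        )
        assert 0.03 <= t_hits / n_rep <= 0.07
        mwu_hits = sum(
            stats.mann_whitney_u(a[i], b[i]).p_value < 0.05 for i in range(n_rep)
        )
        assert 0.03 <= mwu_hits / n_rep <= 0.07


class TestCorrelation:
    def test_linear_relation_perfect_pearson(self):
        x = np.arange(10.0)
        res = stats.correlation(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman_one_pearson_below(self):
        x = np.arange(1.0, 9.0)
        y = np.exp(x)
        assert stats.correlation(x, y, "spearman").statistic == pytest.approx(1.0)
        assert stats.correlation(x, y, "pearson").statistic < 1.0

    def test_matches_direct_covariance_formula(self):
        x = np.array([1.2, 3.4, 2.2, 5.5, 4.1])
        y = np.array([0.7, 2.9, 1.5, 4.2, 4.0])
        r = stats.correlation(x, y).statistic
        direct = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            stats.correlation([1, 1, 1], [1, 2, 3])


class TestUndetectedDiversity:
    def test_survey_extrapolation(self):
        est = stats.undetected_diversity(60, 0.06, 0.12)
        assert est.undetected == pytest.approx(120.0)
        assert est.detected_share == pytest.approx(1 / 3)

    def test_equal_fractions_double_nothing(self):
        est = stats.undetected_diversity(80, 0.1, 0.1)
        assert est.undetected == pytest.approx(80.0)
        assert est.detected_share == pytest.approx(0.5)

    def test_direct_value(self):
        assert stats.undetected_diversity(100, 0.10, 0.05).undetected == pytest.approx(50.0)

    def test_linear_in_detected_and_f_other(self):
        base = stats.undetected_diversity(50, 0.08, 0.12).undetected
        assert stats.undetected_diversity(100, 0.08, 0.12).undetected == pytest.approx(2 * base)
        assert stats.undetected_diversity(50, 0.08, 0.24).undetected == pytest.approx(2 * base)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            stats.undetected_diversity(10, 0.0, 0.1)
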