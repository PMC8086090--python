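"""Priors, configuration likelihoods, and the likelihood-ratio statistic."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import mars
from mars.errors import InvalidInputError, InvalidParameterError

from conftest import dense_lrt, random_correlation


class TestCausalPrior:
    @pytest.mark.parametrize(
        "status, expected",
        [
            ([0, 0, 0], 0.99**3),
            ([1, 0, 0], 0.01 * 0.99**2),
            ([1, 1, 1], 0.01**3),
        ],
    )
    def test_direct_products(self, status, expected):
        cfg = mars.CausalConfig(np.array(status))
        assert mars.causal_prior(cfg, 0.01) == pytest.approx(expected, rel=1e-12)

    @given(m=st.integers(1, 10), gamma=st.floats(0.001, 0.999))
    @settings(max_examples=30, deadline=None)
    def test_normalizes_over_all_configs(self, m, gamma):
        total = sum(
            mars.causal_prior(np.array(bits), gamma)
            for bits in itertools.product([0, 1], repeat=m)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_per_snp_gamma_vector(self):
        g = np.array([0.1, 0.2, 0.3])
        p = mars.causal_prior(np.array([1, 0, 1]), g)
        assert p == pytest.approx(0.1 * 0.8 * 0.3, rel=1e-12)

    @pytest.mark.parametrize("gamma", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_invalid_gamma(self, gamma):
        with pytest.raises(InvalidParameterError):
            mars.causal_prior(np.array([1, 0]), gamma)


class TestConfigCovariance:
    def test_identity_ld_adds_sigma2_on_causal_diagonal(self):
        p = mars.ModelParams(sigma2=25.0, epsilon=0.0, max_causal=1, top_k=2)
        cov = mars.config_covariance(np.eye(2), mars.CausalConfig([1, 0]), p)
        np.testing.assert_allclose(cov, np.diag([26.0, 1.0]))

    def test_null_config_returns_ld(self):
        p = mars.ModelParams(sigma2=25.0, epsilon=0.0, max_causal=1, top_k=2)
        cov = mars.config_covariance(np.eye(2), mars.CausalConfig([0, 0]), p)
        np.testing.assert_allclose(cov, np.eye(2))

    def test_correlated_ld_rank_one_update(self):
        # Sigma + sigma2 * sigma_1 sigma_1' with sigma_1 the causal column
        ld = np.array([[1.0, 0.5], [0.5, 1.0]])
        p = mars.ModelParams(sigma2=25.0, epsilon=0.0, max_causal=1, top_k=2)
        cov = mars.config_covariance(ld, mars.CausalConfig([1, 0]), p)
        expected = ld + 25.0 * np.outer(ld[:, 0], ld[:, 0])
        np.testing.assert_allclose(cov, expected)
        np.testing.assert_allclose(expected, [[26.0, 13.0], [13.0, 7.25]])


class TestConfigLoglik:
    def test_univariate_null(self):
        p = mars.ModelParams(sigma2=25.0, max_causal=1, top_k=1)
        ll = mars.config_loglik(np.array([3.0]), np.eye(1), mars.CausalConfig([0]), p)
        assert ll == pytest.approx(norm.logpdf(3.0), rel=1e-10)

    def test_univariate_causal(self):
        p = mars.ModelParams(sigma2=25.0, max_causal=1, top_k=1)
        ll = mars.config_loglik(np.array([3.0]), np.eye(1), mars.CausalConfig([1]), p)
        assert ll == pytest.approx(norm.logpdf(3.0, scale=np.sqrt(26.0)), rel=1e-10)

    @pytest.mark.parametrize("epsilon", [0.0, 0.2])
    def test_matches_dense_evaluation(self, rng, epsilon):
        from scipy.stats import multivariate_normal

        for _ in range(10):
            m = int(rng.integers(2, 7))
            ld = random_correlation(m, rng)
            s = 2.0 * rng.standard_normal(m)
            p = mars.ModelParams(sigma2=27.04, epsilon=epsilon, max_causal=m, top_k=50)
            idx = rng.choice(m, size=int(rng.integers(1, m + 1)), replace=False)
            status = np.zeros(m, dtype=int)
            status[idx] = 1
            cfg = mars.CausalConfig(status)
            cov = mars.config_covariance(ld, cfg, p)
            expected = multivariate_normal.logpdf(s, mean=np.zeros(m), cov=cov)
            got = mars.config_loglik(s, ld, cfg, p)
            assert got == pytest.approx(expected, rel=1e-8)


class TestSelectTopK:
    def test_ranks_by_absolute_value(self):
        d = mars.LocusData(["a", "b", "c"], [1.2, -3.5, 0.4],
                           mars.gen_ld(3, "ar1", 0.3))
        sub = mars.select_top_k(d, 2)
        assert sub.snp_ids == ["a", "b"]

    def test_identity_when_k_exceeds_m(self):
        ld = mars.gen_ld(10, "ar1", 0.2)
        d = mars.LocusData([f"s{i}" for i in range(10)],
                           np.arange(10, dtype=float), ld)
        assert mars.select_top_k(d, 50) is d

    def test_tie_broken_by_lower_index(self):
        d = mars.LocusData(["a", "b", "c"], [2.0, -2.0, 1.0], np.eye(3))
        sub = mars.select_top_k(d, 2)
        assert sub.snp_ids == ["a", "b"]

    def test_retained_order_is_original_locus_order(self):
        d = mars.LocusData(["a", "b", "c", "d"], [0.5, 4.0, 0.1, 3.0], np.eye(4))
        sub = mars.select_top_k(d, 2)
        assert sub.snp_ids == ["b", "d"]

    def test_signed_ordering_flag(self):
        d = mars.LocusData(["a", "b", "c"], [1.0, -3.0, 2.0], np.eye(3))
        sub = mars.select_top_k(d, 2, by_abs=False)
        assert sub.snp_ids == ["a", "c"]  # largest signed values


class TestEnumerateConfigs:
    def test_locus_wide_count_with_three_causals(self):
        assert mars.n_configs(50, 3) == 20875  # 50 + 1225 + 19600

    @pytest.mark.parametrize("m, max_c, expected",
                             [(3, 3, 7), (5, 1, 5), (6, 2, 21)])
    def test_counts(self, m, max_c, expected):
        configs = list(mars.enumerate_configs(m, max_c))
        assert len(configs) == expected == mars.n_configs(m, max_c)

    def test_unique_and_deterministic_order(self):
        a = [tuple(c.indices) for c in mars.enumerate_configs(5, 2)]
        b = [tuple(c.indices) for c in mars.enumerate_configs(5, 2)]
        assert a == b
        assert len(set(a)) == len(a)
        # by n_causal then lexicographic in the index set
        assert a[:5] == [(0,), (1,), (2,), (3,), (4,)]
        assert a[5] == (0, 1)


class TestLRTStatistic:
    def test_univariate_closed_form(self):
        p = mars.ModelParams(gamma=0.01, sigma2=25.0, max_causal=1, top_k=1)
        d = mars.LocusData(["a"], [3.0], [[1.0]])
        res = mars.lrt_statistic(d, p)
        expected = (0.01 * norm.pdf(3.0, scale=np.sqrt(26.0))) / (
            0.99 * norm.pdf(3.0)
        )
        assert res.lrt_stat == pytest.approx(expected, rel=1e-10)
        assert res.lrt_stat == pytest.approx(0.1500, abs=2e-4)
        assert res.lrt_stat == pytest.approx(
            np.exp(res.log_l1 - res.log_l0), rel=1e-8
        )

    def test_zero_signal_is_prior_determinant_constant(self):
        sigma2 = 25.0
        p = mars.ModelParams(gamma=0.01, sigma2=sigma2, max_causal=1, top_k=1)
        d = mars.LocusData(["a"], [0.0], [[1.0]])
        res = mars.lrt_statistic(d, p)
        expected = (0.01 / 0.99) / np.sqrt(1.0 + sigma2)
        assert res.lrt_stat == pytest.approx(expected, rel=1e-10)
        assert res.lrt_stat < 0.0102

    @pytest.mark.parametrize("epsilon", [0.0, 0.15])
    def test_matches_exhaustive_dense_oracle(self, rng, epsilon):
        for _ in range(15):
            m = int(rng.integers(2, 7))
            ld = random_correlation(m, rng)
            s = 2.0 * rng.standard_normal(m)
            p = mars.ModelParams(sigma2=27.04, epsilon=epsilon, max_causal=m,
                                 top_k=50)
            d = mars.LocusData([f"s{i}" for i in range(m)], s, ld)
            res = mars.lrt_statistic(d, p)
            assert res.lrt_stat == pytest.approx(dense_lrt(s, ld, p), rel=1e-8)
            assert res.n_configs == mars.n_configs(m, m)

    def test_monotone_in_signal_magnitude(self):
        p = mars.ModelParams(max_causal=1, top_k=1)
        values = [
            mars.lrt_statistic(mars.LocusData(["a"], [s], [[1.0]]), p).lrt_stat
            for s in np.linspace(0.0, 6.0, 13)
        ]
        assert np.all(np.diff(values) > 0)

    def test_permutation_equivariance(self, rng):
        m = 8
        ld = random_correlation(m, rng)
        s = 2.0 * rng.standard_normal(m)
        p = mars.ModelParams(max_causal=3, top_k=50)
        base = mars.lrt_statistic(
            mars.LocusData([f"s{i}" for i in range(m)], s, ld), p
        ).lrt_stat
        for _ in range(5):
            perm = rng.permutation(m)
            permuted = mars.lrt_statistic(
                mars.LocusData([f"s{i}" for i in perm], s[perm],
                               ld[np.ix_(perm, perm)]),
                p,
            ).lrt_stat
            assert permuted == pytest.approx(base, rel=1e-10)

    def test_truncation_records_selected_indices(self, rng):
        m = 30
        ld = mars.gen_ld(m, "ar1", 0.4)
        s = rng.standard_normal(m)
        s[7] = 6.0
        p = mars.ModelParams(max_causal=2, top_k=10)
        res = mars.lrt_statistic(mars.LocusData([f"s{i}" for i in range(m)], s, ld), p)
        assert len(res.selected_indices) == 10
        assert 7 in res.selected_indices
        assert res.n_configs == mars.n_configs(10, 2)

    def test_near_singular_ld_warns_and_survives(self):
        ld = np.array([[1.0, 1.0], [1.0, 1.0]])  # perfect LD
        p = mars.ModelParams(max_causal=1, top_k=2)
        with pytest.warns(RuntimeWarning, match="ridge"):
            res = mars.lrt_statistic(mars.LocusData(["a", "b"], [2.0, 2.0], ld), p)
        assert np.isfinite(res.lrt_stat) and res.lrt_stat > 0


class TestLocusDataValidation:
    def test_rejects_asymmetric_ld(self):
        ld = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(InvalidInputError, match="symmetric"):
            mars.LocusData(["a", "b"], [0.0, 0.0], ld)

    def test_rejects_bad_diagonal(self):
        ld = np.array([[1.0, 0.2], [0.2, 0.9]])
        with pytest.raises(InvalidInputError, match="diagonal"):
            mars.LocusData(["a", "b"], [0.0, 0.0], ld)

    def test_rejects_duplicate_ids(self):
        with pytest.raises(InvalidInputError, match="unique"):
            mars.LocusData(["a", "a"], [0.0, 0.0], np.eye(2))

    def test_rejects_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            mars.LocusData(["a", "b", "c"], [0.0, 0.0], np.eye(2))


class TestModelParamsValidation:
    def test_epsilon_must_stay_below_sigma2(self):
        with pytest.raises(InvalidParameterError):
            mars.ModelParams(sigma2=1.0, epsilon=1.0)

    def test_max_causal_bounded_by_top_k(self):
        with pytest.raises(InvalidParameterError):
            mars.ModelParams(max_causal=10, top_k=5)
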