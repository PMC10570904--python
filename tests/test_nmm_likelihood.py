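"""Marginalized likelihood against brute-force enumeration, and HSGP fidelity."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from ctdensity._gp import sqexp_kernel
from ctdensity.nmm import hsgp_basis, log_marginal_obs
from ctdensity.nmm.likelihood import SpeciesCounts


def brute_force_log_marginal(y, lam, p, K, family):
    """Independent oracle: explicit scipy-pmf sum over the latent grid."""
    y = np.asarray(y)
    terms = []
    for N in range(K + 1):
        lp = stats.poisson.logpmf(N, lam)
        if family == "poisson":
            lp += stats.poisson.logpmf(y, N * p).sum()
        else:
            lp += stats.binom.logpmf(y, N, p).sum()
        terms.append(lp)
    return logsumexp(terms)


class TestLogMarginalObs:
    def test_empty_site_limit(self):
        # lam -> 0 with all-zero counts: probability -> 1
        assert log_marginal_obs([0, 0, 0], 1e-12, 0.4, 50) == pytest.approx(0.0, abs=1e-9)

    def test_single_count_hand_enumeration(self):
        val = log_marginal_obs([1], 1.0, 0.5, 50)
        s = sum(
            math.exp(-1) / math.factorial(N) * math.exp(-N * 0.5) * (N * 0.5)
            for N in range(51)
        )
        assert val == pytest.approx(math.log(s), abs=1e-12)

    @pytest.mark.parametrize("family", ["poisson", "binomial"])
    def test_randomized_cases_match_brute_force(self, family, rng):
        for _ in range(50):
            lam = rng.uniform(0.05, 20.0)
            p = rng.uniform(0.05, 0.95)
            J = int(rng.integers(1, 8))
            N_true = rng.poisson(lam)
            if family == "poisson":
                y = rng.poisson(N_true * p, size=J)
            else:
                y = rng.binomial(N_true, p, size=J)
            K = int(y.max(initial=0)) + 100
            ours = log_marginal_obs(y, lam, p, K, family)
            oracle = brute_force_log_marginal(y, lam, p, K, family)
            assert abs(ours - oracle) < 1e-12

    def test_truncation_insensitivity(self, rng):
        for _ in range(20):
            lam = rng.uniform(0.1, 20.0)
            p = rng.uniform(0.1, 0.9)
            y = rng.poisson(lam * p, size=5)
            K = int(y.max(initial=0)) + 100
            a = log_marginal_obs(y, lam, p, K)
            b = log_marginal_obs(y, lam, p, K + 100)
            assert abs(a - b) < 1e-10

    def test_binomial_k_below_max_raises(self):
        with pytest.raises(ValueError):
            log_marginal_obs([5], 1.0, 0.5, 3, "binomial")

    def test_binomial_certain_detection_reduces_to_poisson_pmf(self):
        # p -> 1, J = 1: y = N observed, so the marginal is Poisson(y; lam)
        lam, y = 3.0, 4
        val = log_marginal_obs([y], lam, 1.0 - 1e-12, 120, "binomial")
        assert val == pytest.approx(stats.poisson.logpmf(y, lam), abs=1e-6)


class TestVectorizedAgainstScalar:
    @pytest.mark.parametrize("family", ["poisson", "binomial"])
    def test_unitwise_agreement(self, family, rng):
        R, J, T = 6, 5, 3
        y = rng.poisson(1.5, size=(R, J, T))
        effort = rng.random((R, J, T)) < 0.8
        y = np.where(effort, y, 0)
        sc = SpeciesCounts.from_arrays(y, effort, family=family)
        log_lam = rng.normal(0.5, 0.4, size=sc.n_units)
        p = rng.uniform(0.2, 0.8, size=sc.n_units)
        ll_fast = sc.loglik(log_lam, p)
        ll_np = sc._loglik_grad_numpy(log_lam, p)[0]
        np.testing.assert_allclose(ll_fast, ll_np, atol=1e-12)
        for u in range(sc.n_units):
            i, t = sc.site_idx[u], sc.year_idx[u]
            ref = log_marginal_obs(
                y[i, effort[i, :, t], t], math.exp(log_lam[u]), p[u], sc.K, family
            )
            assert ll_fast[u] == pytest.approx(ref, abs=1e-10)

    def test_gradients_match_finite_differences(self, rng):
        y = rng.poisson(2.0, size=(5, 6, 2))
        effort = np.ones((5, 6, 2), bool)
        sc = SpeciesCounts.from_arrays(y, effort)
        log_lam = rng.normal(0.7, 0.3, sc.n_units)
        p = rng.uniform(0.2, 0.8, sc.n_units)
        _, d_lam, d_p = sc.loglik_grad(log_lam, p)
        eps = 1e-6
        for u in range(0, sc.n_units, 3):
            e = np.zeros(sc.n_units)
            e[u] = eps
            fd = (sc.loglik(log_lam + e, p)[u] - sc.loglik(log_lam - e, p)[u]) / (2 * eps)
            assert d_lam[u] == pytest.approx(fd, rel=1e-5, abs=1e-7)
            fd = (sc.loglik(log_lam, p + e)[u] - sc.loglik(log_lam, p - e)[u]) / (2 * eps)
            assert d_p[u] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestBetaReparameterization:
    def test_mean_and_variance(self, rng):
        n = 200_000
        for p_t in (0.1, 0.3, 0.5, 0.8):
            for tau in (0.5, 2.0, 10.0):
                x = rng.beta(p_t * tau, (1 - p_t) * tau, size=n)
                se_mean = x.std() / math.sqrt(n)
                assert abs(x.mean() - p_t) < 3 * se_mean
                target_var = p_t * (1 - p_t) / (tau + 1)
                se_var = np.var((x - p_t) ** 2) ** 0.5 / math.sqrt(n)
                assert abs(x.var() - target_var) < 3 * se_var + 1e-6


class TestHSGP:
    def test_zero_weights_zero_field(self, rng):
        X = rng.random((10, 2))
        basis = hsgp_basis(X, m=5)
        field = basis.phi @ (basis.sqrt_spd(0.3) * np.zeros(basis.n_basis))
        np.testing.assert_array_equal(field, 0.0)

    @pytest.mark.parametrize("m", [20, 30])
    def test_implied_covariance_matches_exact_kernel(self, m, rng):
        # lengthscale within a third of the data half-width: the default
        # boundary factor suffices
        X = rng.random((25, 2))
        basis = hsgp_basis(X, m=m, c=1.5, half_widths=np.array([0.5, 0.5]))
        approx = basis.implied_cov(lengthscale=0.15, marginal_sd=1.0)
        exact = sqexp_kernel(X, 1.0, 0.15)
        rel = np.linalg.norm(approx - exact) / np.linalg.norm(exact)
        assert rel < 0.02

    def test_long_lengthscale_needs_larger_boundary_factor(self, rng):
        # at lengthscale 0.4 the c = 1.5 boundary is too tight (the
        # eigenbasis imposes zero boundary conditions within reach of the
        # kernel); inflating the domain restores fidelity
        X = rng.random((25, 2))
        exact = sqexp_kernel(X, 1.0, 0.4)

        def rel_err(c):
            b = hsgp_basis(X, m=30, c=c, half_widths=np.array([0.5, 0.5]))
            return np.linalg.norm(b.implied_cov(0.4) - exact) / np.linalg.norm(exact)

        assert rel_err(1.5) > 0.05
        assert rel_err(3.0) < 0.02

    def test_translation_invariance_of_implied_covariance(self, rng):
        X = rng.random((15, 2))
        b1 = hsgp_basis(X, m=12, half_widths=np.array([0.6, 0.6]))
        b2 = hsgp_basis(X + 17.3, m=12, half_widths=np.array([0.6, 0.6]))
        c1 = b1.implied_cov(0.3)
        c2 = b2.implied_cov(0.3)
        assert np.max(np.abs(c1 - c2)) < 1e-6

    def test_too_few_basis_or_small_boundary_raises(self, rng):
        X = rng.random((5, 2))
        with pytest.raises(ValueError):
            hsgp_basis(X, m=1)
        with pytest.raises(ValueError):
            hsgp_basis(X, c=1.0)
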