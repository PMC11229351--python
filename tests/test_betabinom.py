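import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import expit

from asemap.betabinom import (
    GeneDesign,
    betabinom_logpmf,
    estimate_phi,
    loglik,
    loglik_grad_hess,
    mixture_mean,
    phi_moment_estimate,
)


def quadrature_logpmf(y, n, p, phi):
    """Independent oracle: integrate Binomial(n, q) against Beta(q; a, b)."""
    c = (1 - phi) / phi
    a, b = p * c, (1 - p) * c

    def integrand(q):
        return scipy.stats.binom.pmf(y, n, q) * scipy.stats.beta.pdf(q, a, b)

    val, _ = quad(integrand, 0, 1, epsabs=1e-13, epsrel=1e-13, limit=200)
    return np.log(val)


def random_design(rng, S=50, K=2, L=3, shared=False):
    A = rng.dirichlet(np.ones(K), S)
    X = rng.normal(size=(S, L))
    n = rng.integers(1, 25, S)
    y = rng.binomial(n, 0.5)
    cts = np.array([f"ct{k}" for k in range(K)], dtype=object)
    return GeneDesign(
        "g", y, n, A, X, cell_types=cts, shared_spline=shared
    )


class TestLogPmf:
    def test_uniform_case(self):
        # p=0.5, phi=1/3 gives Beta(1,1): discrete uniform over 0..4
        assert betabinom_logpmf(2, 4, 0.5, 1 / 3) == pytest.approx(np.log(1 / 5), abs=1e-12)

    def test_phi_zero_is_exact_binomial(self):
        for y, n, p in [(0, 10, 0.3), (5, 17, 0.42), (17, 17, 0.9)]:
            assert betabinom_logpmf(y, n, p, 0.0) == pytest.approx(
                scipy.stats.binom.logpmf(y, n, p), abs=1e-12
            )

    def test_matches_quadrature_oracle(self):
        assert betabinom_logpmf(5, 17, 0.3, 0.2) == pytest.approx(
            quadrature_logpmf(5, 17, 0.3, 0.2), abs=1e-10
        )

    def test_matches_scipy_reference_parameterization(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            y = int(rng.integers(0, n + 1))
            p = rng.uniform(0.05, 0.95)
            phi = rng.uniform(0.01, 0.9)
            c = (1 - phi) / phi
            ref = scipy.stats.betabinom.logpmf(y, n, p * c, (1 - p) * c)
            assert betabinom_logpmf(y, n, p, phi) == pytest.approx(ref, abs=1e-10)

    def test_degenerate_p_is_point_mass(self):
        assert betabinom_logpmf(0, 7, 0.0, 0.3) == 0.0
        assert betabinom_logpmf(1, 7, 0.0, 0.3) == -np.inf
        assert betabinom_logpmf(7, 7, 1.0, 0.3) == 0.0

    def test_normalization_small_grid(self):
        for n in (1, 5, 23):
            for p in (0.2, 0.5, 0.9):
                for phi in (0.0, 0.1, 0.7):
                    total = np.exp(betabinom_logpmf(np.arange(n + 1), n, p, phi)).sum()
                    assert total == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        st.integers(1, 40),
        st.floats(0.01, 0.99),
        st.floats(0.0, 0.95),
        st.integers(0, 2**31 - 1),
    )
    def test_symmetry_in_alleles(self, n, p, phi, seed):
        y = np.random.default_rng(seed).integers(0, n + 1)
        assert betabinom_logpmf(y, n, p, phi) == pytest.approx(
            betabinom_logpmf(n - y, n, 1 - p, phi), abs=1e-9
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            betabinom_logpmf(5, 4, 0.5, 0.1)
        with pytest.raises(ValueError):
            betabinom_logpmf(1, 4, 0.5, 1.0)
        with pytest.raises(ValueError):
            betabinom_logpmf(1, 4, 1.5, 0.1)


class TestMixtureMean:
    def test_null_intercept_gives_half(self):
        d = GeneDesign("g", [1], [2], np.ones((1, 1)), np.zeros((1, 0)))
        assert mixture_mean(np.zeros(1), d)[0] == pytest.approx(0.5)

    def test_saturated_expits(self):
        d = GeneDesign(
            "g", [1], [2], np.array([[0.25, 0.75]]), np.zeros((1, 0)),
            cell_types=np.array(["a", "b"], dtype=object),
        )
        p = mixture_mean(np.array([15.0, -15.0]), d)
        assert p[0] == pytest.approx(0.25, abs=1e-5)

    def test_matches_per_spot_loop_oracle(self):
        rng = np.random.default_rng(1)
        d = random_design(rng, S=40, K=3, L=4, shared=False)
        beta = rng.normal(0, 0.8, d.n_params)
        p = mixture_mean(beta, d)
        # naive loop over spots and cell types
        K, L = 3, 4
        intercepts = beta[:K]
        blocks = beta[K:].reshape(K, L)
        for i in range(d.S):
            pi = 0.0
            for k in range(K):
                eta = intercepts[k] + d.X[i] @ blocks[k]
                pi += d.A[i, k] * expit(np.clip(eta, -15, 15))
            assert p[i] == pytest.approx(pi, abs=1e-12)

    def test_parameter_length_mismatch_errors(self):
        d = GeneDesign("g", [1], [2], np.ones((1, 1)), np.zeros((1, 0)))
        with pytest.raises(ValueError, match="length"):
            mixture_mean(np.zeros(3), d)


class TestDerivatives:
    @pytest.mark.parametrize("shared", [False, True])
    @pytest.mark.parametrize("phi", [0.0, 0.2])
    def test_gradient_matches_central_differences(self, shared, phi):
        rng = np.random.default_rng(2)
        d = random_design(rng, S=60, K=2, L=3, shared=shared)
        beta = rng.normal(0, 0.5, d.n_params)
        _, g, _ = loglik_grad_hess(beta, phi, d)
        eps = 1e-5
        for i in range(d.n_params):
            e = np.zeros(d.n_params)
            e[i] = eps
            fd = (loglik(beta + e, phi, d) - loglik(beta - e, phi, d)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_hessian_symmetric_and_matches_gradient_differences(self):
        rng = np.random.default_rng(3)
        d = random_design(rng, S=50, K=2, L=2)
        beta = rng.normal(0, 0.5, d.n_params)
        _, _, H = loglik_grad_hess(beta, 0.15, d)
        assert np.abs(H - H.T).max() < 1e-10
        eps = 1e-5
        for i in range(d.n_params):
            e = np.zeros(d.n_params)
            e[i] = eps
            _, gp, _ = loglik_grad_hess(beta + e, 0.15, d)
            _, gm, _ = loglik_grad_hess(beta - e, 0.15, d)
            np.testing.assert_allclose(H[i], (gp - gm) / (2 * eps), rtol=1e-4, atol=1e-6)

    def test_loglik_invariant_to_cell_type_permutation(self):
        rng = np.random.default_rng(4)
        d = random_design(rng, S=40, K=3, L=2, shared=False)
        beta = rng.normal(0, 0.5, d.n_params)
        ll = loglik(beta, 0.1, d)
        perm = [2, 0, 1]
        d_p = GeneDesign(
            "g", d.y, d.n, d.A[:, perm], d.X,
            cell_types=d.cell_types[perm], shared_spline=False,
        )
        K, L = 3, 2
        beta_p = np.concatenate(
            [beta[:K][perm], beta[K:].reshape(K, L)[perm].ravel()]
        )
        assert loglik(beta_p, 0.1, d_p) == pytest.approx(ll, abs=1e-10)


class TestPhiEstimation:
    def _simulate(self, rng, phi, S=2000, n_mean=15):
        n = rng.poisson(n_mean, S) + 1
        p = 0.5
        if phi == 0:
            y = rng.binomial(n, p)
        else:
            c = (1 - phi) / phi
            q = rng.beta(p * c, (1 - p) * c, S)
            y = rng.binomial(n, q)
        A = np.ones((S, 1))
        return GeneDesign("g", y, n, A, np.zeros((S, 0)))

    def test_recovers_known_phi(self):
        rng = np.random.default_rng(5)
        d = self._simulate(rng, 0.3)
        est = estimate_phi(np.zeros(1), d)
        assert abs(est.phi - 0.3) < 0.05

    def test_binomial_data_estimates_near_zero(self):
        rng = np.random.default_rng(6)
        d = self._simulate(rng, 0.0)
        est = estimate_phi(np.zeros(1), d)
        assert est.phi < 0.01

    def test_all_singleton_counts_flagged_flat(self):
        rng = np.random.default_rng(7)
        n = np.ones(100, dtype=int)
        y = rng.binomial(n, 0.5)
        d = GeneDesign("g", y, n, np.ones((100, 1)), np.zeros((100, 0)))
        est = estimate_phi(np.zeros(1), d)
        assert est.flat and est.at_boundary

    def test_moment_estimate_in_bounds(self):
        rng = np.random.default_rng(8)
        d = self._simulate(rng, 0.4)
        phi0 = phi_moment_estimate(d.y, d.n)
        assert 0 < phi0 < 1
        assert abs(phi0 - 0.4) < 0.1


class TestIntercerptOnlyMLE:
    def test_mle_equals_weighted_moment_solution(self):
        """For K=1 intercept-only at fixed phi, the score in beta0 vanishes
        exactly at the pooled weighted fraction; cross-check by grid search."""
        rng = np.random.default_rng(9)
        n = rng.integers(1, 12, 80)
        y = rng.binomial(n, 0.37)
        d = GeneDesign("g", y, n, np.ones((80, 1)), np.zeros((80, 0)))
        grid = np.linspace(-3, 3, 4001)
        lls = [loglik(np.array([b]), 0.0, d) for b in grid]
        b_grid = grid[int(np.argmax(lls))]
        p_grid = expit(b_grid)
        assert p_grid == pytest.approx(y.sum() / n.sum(), abs=2e-3)
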