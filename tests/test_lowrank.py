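"""Classical solver tests: embeddings, proximal operators (against
brute-force minimization oracles), the alternating decomposition and the
surrogate noise update."""

import numpy as np
import pytest
from scipy.optimize import minimize

import eegunfold as eu
from eegunfold.lowrank import _objective


def prox_nuclear_bruteforce(M, alpha):
    """Numerical minimizer of alpha*||X||_* + 0.5*||X - M||_F^2.

    The nuclear norm is smoothed (sum of sqrt(sigma^2 + eps)) and the
    smoothing is annealed toward zero with L-BFGS warm starts, which
    minimizes the defining objective without ever invoking the
    singular-value shrinkage formula under test.
    """
    X0 = M.ravel().copy()
    for eps in (1e-2, 1e-5, 1e-8, 1e-12):

        def f_and_g(flat):
            X = flat.reshape(M.shape)
            U, s, Vt = np.linalg.svd(X, full_matrices=False)
            f = alpha * np.sum(np.sqrt(s**2 + eps)) + 0.5 * np.sum((X - M) ** 2)
            g = alpha * (U * (s / np.sqrt(s**2 + eps))) @ Vt + (X - M)
            return f, g.ravel()

        res = minimize(f_and_g, X0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12})
        X0 = res.x
    return X0.reshape(M.shape)


def prox_l1_bruteforce(v, tau):
    """Per-coordinate numerical minimizer of tau*|u| + 0.5*(u - v)^2."""
    out = np.empty_like(v)
    grid = np.linspace(-3 * np.abs(v).max() - 1, 3 * np.abs(v).max() + 1, 200001)
    for i, vi in enumerate(v):
        vals = tau * np.abs(grid) + 0.5 * (grid - vi) ** 2
        out[i] = grid[np.argmin(vals)]
    return out


class TestEmbedding:
    def test_reshape_roundtrip(self, rng):
        s = eu.Segment1D(rng.standard_normal(512))
        spec = eu.WindowEmbedding(16, 32, "reshape")
        back = eu.unembed(eu.embed(s, spec), spec, fs=s.fs)
        assert np.array_equal(back.samples, s.samples)

    def test_hankel_roundtrip(self, rng):
        s = eu.Segment1D(rng.standard_normal(101))
        spec = eu.WindowEmbedding(32, 70, "hankel")
        back = eu.unembed(eu.embed(s, spec), spec, fs=s.fs)
        assert np.allclose(back.samples, s.samples, atol=1e-12)

    def test_hankel_constant_is_rank_one(self):
        s = eu.Segment1D(np.full(63, 3.5))
        M = eu.embed(s, eu.WindowEmbedding(32, 32, "hankel"))
        assert np.all(M == 3.5)
        assert np.linalg.matrix_rank(M) == 1

    def test_sinusoid_reshape_rank_two(self):
        # integer periods per row -> every row is the same sinusoid cycle
        t = np.arange(512)
        s = eu.Segment1D(np.sin(2 * np.pi * 4 * t / 32))
        M = eu.embed(s, eu.WindowEmbedding(16, 32, "reshape"))
        sv = np.linalg.svd(M, compute_uv=False)
        assert np.all(sv[2:] < 1e-8 * sv[0])

    def test_inconsistent_spec_raises(self, rng):
        s = eu.Segment1D(rng.standard_normal(512))
        with pytest.raises(ValueError):
            eu.embed(s, eu.WindowEmbedding(16, 31, "reshape"))
        with pytest.raises(ValueError):
            eu.embed(s, eu.WindowEmbedding(16, 32, "hankel"))


class TestSVT:
    def test_diagonal_case(self):
        M = np.diag([5.0, 1.0])
        out = eu.svt(M, 2.0)
        assert np.allclose(out, np.diag([3.0, 0.0]), atol=1e-12)

    def test_zero_threshold_is_identity(self, rng):
        M = rng.standard_normal((4, 6))
        assert np.allclose(eu.svt(M, 0.0), M)

    def test_nuclear_norm_shrinkage(self, rng):
        M = rng.standard_normal((5, 5))
        alpha = 0.4
        sv_in = np.linalg.svd(M, compute_uv=False)
        sv_out = np.linalg.svd(eu.svt(M, alpha), compute_uv=False)
        assert sv_out.sum() == pytest.approx(np.maximum(sv_in - alpha, 0).sum(), abs=1e-10)

    def test_matches_bruteforce_proximal_oracle(self, rng):
        M = rng.standard_normal((4, 4))
        oracle = prox_nuclear_bruteforce(M, 0.7)
        assert np.allclose(eu.svt(M, 0.7), oracle, atol=1e-5)


class TestSoftThreshold:
    @pytest.mark.parametrize("v,tau,expected", [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0)])
    def test_scalar_cases(self, v, tau, expected):
        assert eu.soft_threshold(np.array([v]), tau)[0] == expected

    def test_zero_tau_identity(self, rng):
        v = rng.standard_normal(10)
        assert np.array_equal(eu.soft_threshold(v, 0.0), v)

    def test_negative_tau_raises(self):
        with pytest.raises(ValueError):
            eu.soft_threshold(np.ones(3), -0.1)

    def test_matches_bruteforce_proximal_oracle(self, rng):
        v = rng.standard_normal(10)
        oracle = prox_l1_bruteforce(v, 0.3)
        assert np.allclose(eu.soft_threshold(v, 0.3), oracle, atol=1e-4)


class TestRPCADecompose:
    def test_noise_free_low_rank_input(self, rng):
        u, v = rng.standard_normal(16), rng.standard_normal(16)
        R = np.outer(u, v)
        res = eu.rpca_decompose(R, eu.LRRSolverConfig(mu=50.0, beta=200.0))
        assert np.abs(res.N).max() < 1e-8
        assert np.linalg.norm(res.D - R) / np.linalg.norm(R) < 1e-2

    def test_zero_input(self):
        res = eu.rpca_decompose(np.zeros((8, 8)))
        assert np.all(res.D == 0) and np.all(res.N == 0)

    def test_objective_nonincreasing(self, rng):
        R = rng.standard_normal((16, 16))
        res = eu.rpca_decompose(R, eu.LRRSolverConfig(mu=0.3, beta=5.0, max_iter=100))
        h = np.asarray(res.objective_history)
        assert np.all(np.diff(h) <= 1e-10)

    def test_rank2_plus_sparse_recovery(self):
        rng = np.random.default_rng(11)
        L = np.outer(rng.standard_normal(32), rng.standard_normal(32)) + np.outer(
            rng.standard_normal(32), rng.standard_normal(32)
        )
        S = np.zeros((32, 32))
        support = rng.random((32, 32)) < 0.05
        S[support] = 5.0 * rng.choice([-1.0, 1.0], size=int(support.sum()))
        res = eu.rpca_decompose(
            L + S, eu.LRRSolverConfig(mu=0.18, beta=20.0, max_iter=500)
        )
        rel = np.linalg.norm(res.D - L) / np.linalg.norm(L)
        assert rel <= 1e-2
        assert res.iterations_run <= 500


class TestSurrogateUpdate:
    def test_half_weights_when_mu_ls_equals_beta(self, rng):
        N_prev = rng.standard_normal((4, 4))
        R_prev = rng.standard_normal((4, 4))
        D_cur = rng.standard_normal((4, 4))
        out = eu.surrogate_update_n(
            N_prev, R_prev, D_cur, mu=2.0, beta=2.0, ls=1.0, grad_s=lambda n: 0 * n
        )
        assert np.allclose(out, 0.5 * N_prev + 0.5 * (R_prev - D_cur), atol=1e-12)

    def test_fixed_point(self, rng):
        R_prev = rng.standard_normal((4, 4))
        D_cur = rng.standard_normal((4, 4))
        N_prev = R_prev - D_cur
        out = eu.surrogate_update_n(
            N_prev, R_prev, D_cur, mu=1.3, beta=0.7, ls=2.0, grad_s=lambda n: 0 * n
        )
        assert np.allclose(out, N_prev, atol=1e-12)

    def test_coefficients_sum_to_one(self, rng):
        for _ in range(20):
            mu, beta, ls = rng.uniform(0.1, 10, size=3)
            delta = mu * ls / (mu * ls + beta)
            assert delta + beta / (mu * ls + beta) == pytest.approx(1.0, abs=1e-12)

    def test_matches_numerical_argmin_of_surrogate_objective(self, rng):
        """With quadratic S(N) = 0.5*||N||^2 (grad = identity, ls = 1), the
        closed form must equal the numerical minimizer of
        mu*S_hat(N | N_prev) + (beta/2)*||R - D - N||^2."""
        for _ in range(20):
            N_prev = rng.standard_normal(8)
            R_prev = rng.standard_normal(8)
            D_cur = rng.standard_normal(8)
            mu, beta = rng.uniform(0.2, 5.0, size=2)
            ls = 1.0

            def objective(N):
                s_hat = 0.5 * ls * np.sum((N - N_prev + N_prev / ls) ** 2)
                return mu * s_hat + 0.5 * beta * np.sum((R_prev - D_cur - N) ** 2)

            res = minimize(objective, N_prev, method="BFGS", options={"gtol": 1e-12})
            closed = eu.surrogate_update_n(
                N_prev, R_prev, D_cur, mu=mu, beta=beta, ls=ls, grad_s=lambda n: n
            )
            assert np.allclose(closed, res.x, atol=1e-6)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            eu.surrogate_update_n(
                np.ones(4), np.ones(5), np.ones(4), 1.0, 1.0, 1.0, lambda n: n
            )


class TestClassicalDenoise:
    def test_clean_sinusoid_recovered(self):
        t = np.arange(512)
        y = eu.Segment1D(np.sin(2 * np.pi * 4 * t / 32))
        x_hat, _ = eu.classical_denoise(
            y, eu.WindowEmbedding(16, 32), eu.LRRSolverConfig(mu=50.0, beta=500.0)
        )
        assert eu.rrmse_temporal(x_hat, y) < 0.05

    def test_spikes_go_to_noise(self):
        t = np.arange(512)
        clean = np.sin(2 * np.pi * 4 * t / 32)
        y = clean.copy()
        spikes = np.zeros(512)
        for pos in (100, 260, 400):
            spikes[pos] = 8.0
        y += spikes
        _, n_hat = eu.classical_denoise(
            eu.Segment1D(y), eu.WindowEmbedding(16, 32),
            eu.LRRSolverConfig(mu=0.3, beta=20.0),
        )
        spike_energy = np.sum(spikes**2)
        captured = np.sum(n_hat.samples[spikes != 0] ** 2)
        assert captured >= 0.8 * spike_energy

    def test_additivity(self, rng):
        y = eu.Segment1D(rng.standard_normal(512))
        x_hat, n_hat = eu.classical_denoise(y, eu.WindowEmbedding(16, 32))
        assert np.allclose(x_hat.samples + n_hat.samples, y.samples, atol=1e-10)

    def test_bad_spec_raises(self, rng):
        y = eu.Segment1D(rng.standard_normal(100))
        with pytest.raises(ValueError):
            eu.classical_denoise(y, eu.WindowEmbedding(16, 32))
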