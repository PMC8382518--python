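import numpy as np
import pytest
from dataclasses import replace

from g3cs import (
    RunConfig,
    compute_G,
    fit,
    objective,
    update_F,
    update_P,
    update_Z,
)
from g3cs.data_io import ValidationError
from g3cs.gene_correlation import (
    AdjustedCorrelation,
    adjust_correlation,
    covariance_matrix,
)
from g3cs.sample_graph import SimilarityGraph, graph_laplacian
from g3cs.solver import SolverState


def _identity_adj(m):
    return AdjustedCorrelation(np.eye(m), mode="printed", symmetrized=True)


def _random_lap(n, seed):
    rng = np.random.default_rng(seed)
    S = rng.uniform(0, 1, size=(n, n))
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 0)
    return graph_laplacian(SimilarityGraph(S, k=n - 1, t=1.0))


class TestObjective:
    def test_exact_factorization_gives_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 5))
        P = rng.normal(size=(4, 2))
        Z = rng.normal(size=(5, 2))
        F = np.eye(2)
        # choose Z so that F Z^T = P^T X exactly
        Z = (P.T @ X).T
        state = SolverState(P=P, F=F, Z=np.abs(Z) * 0 + Z, G=np.eye(4))
        cfg = RunConfig(alpha=0.0, beta=0.0, gamma=0.0, c=2)
        parts = objective(X, state, _identity_adj(4), _random_lap(5, 1), cfg)
        assert parts.total == pytest.approx(0, abs=1e-18)

    def test_l21_term_by_hand(self):
        X = np.eye(2)
        P = np.array([[3.0, 4.0], [0.0, 0.0]])
        F = np.eye(2)
        Z = (P.T @ X).T  # kills the residual
        state = SolverState(P=P, F=F, Z=Z, G=np.eye(2))
        cfg = RunConfig(alpha=1.0, beta=0.0, gamma=0.0, c=2)
        parts = objective(X, state, _identity_adj(2), _random_lap(2, 2), cfg)
        assert parts.sparsity == pytest.approx(5.0)
        assert parts.total == pytest.approx(5.0)

    def test_matches_single_expression_oracle(self):
        rng = np.random.default_rng(3)
        m, n, c = 6, 5, 2
        X = rng.normal(size=(m, n))
        P = rng.normal(size=(m, c))
        F = rng.normal(size=(c, c))
        Z = np.abs(rng.normal(size=(n, c)))
        adj = AdjustedCorrelation(
            rng.normal(size=(m, m)), mode="printed", symmetrized=False
        )
        lap = _random_lap(n, 4)
        cfg = RunConfig(alpha=0.7, beta=0.3, gamma=1.9, c=c)
        state = SolverState(P=P, F=F, Z=Z, G=np.eye(m))
        parts = objective(X, state, adj, lap, cfg)
        oracle = (
            np.linalg.norm(P.T @ X - F @ Z.T, "fro") ** 2
            + 0.7 * np.linalg.norm(P, axis=1).sum()
            + 0.3 * np.trace(P.T @ adj.M_bar @ P)
            + 1.9 * np.trace(Z.T @ lap.L @ Z)
        )
        assert parts.total == pytest.approx(oracle, rel=1e-12)


class TestComputeG:
    def test_known_row_norm(self):
        G = compute_G(np.array([[3.0, 4.0]]), 1e-8)
        assert G[0, 0] == pytest.approx(0.1)

    def test_zero_row_floored(self):
        G = compute_G(np.array([[0.0, 0.0]]), 1e-8)
        assert G[0, 0] == pytest.approx(5e7)

    def test_homogeneity_above_floor(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(5, 3))
        np.testing.assert_allclose(
            np.diag(compute_G(2 * P, 1e-12)), np.diag(compute_G(P, 1e-12)) / 2
        )


class TestUpdateP:
    def test_identity_collapse(self):
        rng = np.random.default_rng(1)
        n = 4
        X = np.eye(n)
        Z = rng.normal(size=(n, 2))
        F = rng.normal(size=(2, 2))
        P = update_P(X, Z, F, np.zeros((n, n)), _identity_adj(n), 0.0, 0.0)
        np.testing.assert_allclose(P, Z @ F.T, atol=1e-10)

    def test_normal_equation_residual(self):
        rng = np.random.default_rng(2)
        m, n, c = 6, 5, 2
        X = rng.normal(size=(m, n))
        Z = rng.normal(size=(n, c))
        F = rng.normal(size=(c, c))
        G = compute_G(rng.normal(size=(m, c)), 1e-8)
        adj = adjust_correlation(
            covariance_matrix(
                __import__("g3cs").ExpressionDataset(
                    X, [f"g{i}" for i in range(m)], [f"s{j}" for j in range(n)]
                )
            )
        )
        alpha, beta = 0.5, 0.2
        P = update_P(X, Z, F, G, adj, alpha, beta)
        A = X @ X.T + alpha * G + beta * adj.symmetric_part
        B = X @ Z @ F.T
        rel = np.linalg.norm(A @ P - B) / np.linalg.norm(B)
        assert rel <= 1e-8

    def test_large_beta_shrinks_P(self):
        rng = np.random.default_rng(3)
        m, n, c = 5, 6, 2
        X = rng.normal(size=(m, n))
        Z = rng.normal(size=(n, c))
        F = np.eye(c)
        G = np.eye(m)
        norms = [
            np.linalg.norm(
                update_P(X, Z, F, G, _identity_adj(m), 1.0, beta), "fro"
            )
            for beta in (1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))


class TestUpdateF:
    def test_orthogonal_W_is_fixed_point(self):
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        # build X, P, Z with P^T X Z = R
        X = np.eye(2)
        P = np.eye(2)
        Z = R
        F = update_F(P, X, Z, np.eye(2), method="procrustes")
        np.testing.assert_allclose(F, R, atol=1e-12)
        # stationarity residual of the rho-penalized problem vanishes
        rho = 1e3
        res = -R + F + rho * (F @ F.T @ F - F)
        np.testing.assert_allclose(res, 0, atol=1e-9)

    def test_positive_diagonal_gives_identity(self):
        X = np.eye(2)
        P = np.eye(2)
        Z = np.diag([2.0, 0.5])
        F = update_F(P, X, Z, np.eye(2), method="procrustes")
        np.testing.assert_allclose(F, np.eye(2), atol=1e-12)

    def test_rotation_from_skew_target(self):
        X = np.eye(2)
        P = np.eye(2)
        Z = np.array([[0.0, -3.0], [2.0, 0.0]])
        F = update_F(P, X, Z, np.eye(2), method="procrustes")
        np.testing.assert_allclose(F, [[0, -1], [1, 0]], atol=1e-12)

    def test_procrustes_beats_random_orthogonal_candidates(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            W = rng.normal(size=(3, 3))
            X = np.eye(3)
            F = update_F(np.eye(3), X, W, np.eye(3), method="procrustes")
            best = np.linalg.norm(W - F, "fro")
            for _ in range(200):
                Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
                assert np.linalg.norm(W - Q, "fro") >= best - 1e-10

    def test_multiplicative_variant_is_finite(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(4, 2))
        X = rng.normal(size=(4, 6))
        Z = rng.normal(size=(6, 2))
        F = update_F(P, X, Z, np.eye(2), rho=1e3, method="multiplicative")
        assert np.all(np.isfinite(F))


class TestUpdateZ:
    def _setup(self, n=6, c=2, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(4, n))
        P = rng.normal(size=(4, c))
        F, _ = np.linalg.qr(rng.normal(size=(c, c)))
        Z = np.abs(rng.normal(size=(n, c))) + 0.1
        lap = _random_lap(n, seed + 50)
        return X, P, F, Z, lap

    def test_stays_nonnegative(self):
        X, P, F, Z, lap = self._setup()
        for _ in range(20):
            Z = update_Z(X, P, F, Z, lap, gamma=1.0, kappa=1e3)
            assert np.all(Z >= 0)

    def test_negative_input_rejected(self):
        X, P, F, Z, lap = self._setup()
        Z[0, 0] = -0.1
        with pytest.raises(ValidationError):
            update_Z(X, P, F, Z, lap, gamma=1.0)

    def test_kkt_point_is_fixed(self):
        # iterate to (near) convergence, then one more step barely moves
        X, P, F, Z, lap = self._setup()
        for _ in range(5000):
            Z = update_Z(X, P, F, Z, lap, gamma=0.5, kappa=1e3)
        Z2 = update_Z(X, P, F, Z, lap, gamma=0.5, kappa=1e3)
        assert np.linalg.norm(Z2 - Z) / np.linalg.norm(Z) < 1e-5

    def test_large_kappa_freezes_orthonormal_Z(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 6))
        P = rng.normal(size=(4, 2))
        F = np.eye(2)
        # nonnegative column-orthonormal indicator (disjoint supports)
        Z = np.zeros((6, 2))
        Z[:3, 0] = 1 / np.sqrt(3)
        Z[3:, 1] = 1 / np.sqrt(3)
        lap = _random_lap(6, 2)
        Z2 = update_Z(X, P, F, Z, lap, gamma=0.0, kappa=1e12)
        np.testing.assert_allclose(Z2, Z, rtol=1e-4)

    def test_penalized_lagrangian_does_not_increase(self):
        X, P, F, Z, lap = self._setup(seed=7)
        gamma, kappa = 0.8, 1e3

        def penalized(Zc):
            return (
                np.linalg.norm(P.T @ X - F @ Zc.T, "fro") ** 2
                + gamma * np.trace(Zc.T @ lap.L @ Zc)
                + kappa / 4 * np.linalg.norm(Zc.T @ Zc - np.eye(2), "fro") ** 2
            )

        for _ in range(50):
            before = penalized(Z)
            Z = update_Z(X, P, F, Z, lap, gamma, kappa)
            assert penalized(Z) <= before + 1e-9 * max(abs(before), 1.0)


class TestFit:
    def test_determinism(self, default_synthetic):
        data, _ = default_synthetic
        cfg = RunConfig(c=3, seed=7)
        t1 = fit(data, cfg).objective_trace
        t2 = fit(data, cfg).objective_trace
        assert t1 == t2  # bitwise identical

    def test_trace_non_increasing_after_sweep_two(self, default_synthetic):
        data, _ = default_synthetic
        state = fit(data, RunConfig(c=3, seed=0))
        tr = np.array(state.objective_trace)
        rel = np.diff(tr) / np.maximum(np.abs(tr[:-1]), 1e-12)
        assert rel[2:].max() <= 1e-6
        assert state.converged

    def test_infinite_tol_stops_after_one_sweep(self, default_synthetic):
        data, _ = default_synthetic
        state = fit(data, RunConfig(c=3, seed=0, tol=np.inf))
        assert state.iterations == 1
        assert state.converged

    def test_reweighting_monotone_with_frozen_F_Z(self, default_synthetic):
        # iterating update_P/compute_G alone descends the P-block objective
        data, _ = default_synthetic
        rng = np.random.default_rng(0)
        X = data.values
        m, c = X.shape[0], 3
        adj = adjust_correlation(covariance_matrix(data))
        Z = np.abs(rng.normal(size=(X.shape[1], c)))
        Z, _ = np.linalg.qr(Z)
        Z = np.abs(Z)
        F = np.eye(c)
        alpha, beta = 1.0, 1e-3
        P = rng.normal(size=(m, c))

        def block_obj(P):
            return (
                np.linalg.norm(P.T @ X - F @ Z.T, "fro") ** 2
                + alpha * np.linalg.norm(P, axis=1).sum()
                + beta * np.trace(P.T @ adj.symmetric_part @ P)
            )

        prev = block_obj(P)
        for _ in range(30):
            G = compute_G(P, 1e-8)
            P = update_P(X, Z, F, G, adj, alpha, beta)
            now = block_obj(P)
            assert now <= prev + 1e-9 * max(abs(prev), 1.0)
            prev = now
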