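"""Network estimators: PC, SR, and the alternating noise-aware variants."""

import warnings

import numpy as np
import pytest

from noisefbn import (
    PCAND,
    SRAND,
    PearsonCorrelationNetwork,
    SparseRepresentationNetwork,
    center_normalize,
    joint_objective,
    pc_network,
    sr_network,
    transform_data,
)


class TestPearsonCorrelation:
    def test_duplicate_columns_give_unit_weight(self, rng):
        x = rng.standard_normal(20)
        X = np.column_stack([x, x, rng.standard_normal(20)])
        W = pc_network(X)
        assert np.isclose(W[0, 1], 1.0)

    def test_orthogonal_columns_give_zero(self):
        X = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]])
        # columns zero-mean and mutually orthogonal
        W = pc_network(X)
        assert np.isclose(W[0, 1], 0.0, atol=1e-12)

    def test_hand_computed_correlation(self):
        X = np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0]])
        W = pc_network(X)
        assert np.isclose(W[0, 1], 0.5)

    def test_invariants(self, rng):
        W = pc_network(rng.standard_normal((40, 7)))
        assert np.allclose(W, W.T)
        assert np.allclose(np.diag(W), 1.0)
        assert W.min() >= -1 - 1e-12 and W.max() <= 1 + 1e-12


class TestSparseRepresentation:
    def test_zero_solution_above_activation_threshold(self, small_normalized):
        """On unit-norm columns, lambda1 >= 2 exceeds 2*max|x_j'x_i|."""
        assert np.all(sr_network(small_normalized, 2.0) == 0)
        assert np.all(sr_network(small_normalized, 2.5) == 0)

    def test_lambda_zero_equals_least_squares(self, rng):
        X = center_normalize(rng.standard_normal((50, 6)))
        W = sr_network(X, 0.0)
        for i in range(6):
            idx = np.arange(6) != i
            A = X[:, idx]
            beta = np.linalg.solve(A.T @ A, A.T @ X[:, i])  # normal equations
            assert np.allclose(W[idx, i], beta, atol=1e-8)

    def test_duplicate_roi_dominates(self, rng):
        x1 = rng.standard_normal(40)
        x2 = rng.standard_normal(40)
        X = np.column_stack([x1, x2, x1])  # ROI 2 duplicates ROI 0
        W = sr_network(X, 0.05)
        off = np.abs(W[~np.eye(3, dtype=bool)])
        assert np.abs(W[2, 0]) == pytest.approx(off.max())
        assert np.abs(W[0, 2]) == pytest.approx(off.max())

    def test_zero_diagonal_by_construction(self, small_normalized):
        W = sr_network(small_normalized, 0.1)
        assert np.all(np.diag(W) == 0)

    def test_lasso_kkt_conditions(self, small_normalized):
        """Column solutions satisfy the lasso stationarity conditions."""
        lam = 0.3
        X = small_normalized
        W = sr_network(X, lam, lasso_tol=1e-10)
        for i in range(X.shape[1]):
            idx = np.arange(X.shape[1]) != i
            A, b, w = X[:, idx], X[:, i], W[idx, i]
            g = 2.0 * A.T @ (A @ w - b)
            active = np.abs(w) > 1e-10
            assert np.abs(g[active] + lam * np.sign(w[active])).max() < 1e-4
            assert np.all(np.abs(g[~active]) <= lam + 1e-4)


class TestSRAND:
    def test_single_iteration_reduces_to_sr(self, small_normalized):
        Wsr = sr_network(small_normalized, 0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est = SRAND(0.3, prior="l1", max_outer_iter=1).fit(small_normalized)
        assert np.abs(est.weights_ - Wsr).max() < 1e-6

    @pytest.mark.parametrize("prior", ["l1", "wishart"])
    def test_objective_trace_non_increasing(self, rng, prior):
        X = center_normalize(rng.standard_normal((30, 8)))
        est = SRAND(
            0.3, prior=prior, lambda2=0.1, max_outer_iter=15,
            lasso_tol=1e-8,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est.fit(X)
        trace = est.objective_trace_
        slack = 1e-8 * np.maximum(1.0, np.abs(trace[:-1]))
        assert np.all(np.diff(trace) <= slack)

    @pytest.mark.parametrize("prior", ["l1", "wishart"])
    def test_omega_symmetric_pd(self, rng, prior):
        X = center_normalize(rng.standard_normal((25, 10)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est = SRAND(0.4, prior=prior, max_outer_iter=5).fit(X)
        assert np.allclose(est.omega_, est.omega_.T, atol=1e-8)
        assert np.linalg.eigvalsh(est.omega_).min() > 0

    def test_deterministic(self, small_normalized):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = SRAND(0.3, prior="wishart", max_outer_iter=5).fit(small_normalized)
            b = SRAND(0.3, prior="wishart", max_outer_iter=5).fit(small_normalized)
        assert np.array_equal(a.weights_, b.weights_)
        assert np.array_equal(a.omega_, b.omega_)

    def test_fitted_attributes(self, small_normalized):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est = SRAND(0.5, prior="wishart", max_outer_iter=10).fit(
                small_normalized
            )
        assert est.n_iter_ == len(est.objective_trace_) - 1
        assert est.weights_.shape == (8, 8)
        assert np.all(np.diag(est.weights_) == 0)
        assert isinstance(est.converged_, bool)

    def test_unknown_prior_rejected(self, small_normalized):
        with pytest.raises(ValueError, match="prior"):
            SRAND(0.3, prior="gauss").fit(small_normalized)

    def test_sklearn_params_roundtrip(self):
        est = SRAND(0.7, prior="wishart", alpha=2.0)
        params = est.get_params()
        assert params["lambda1"] == 0.7 and params["alpha"] == 2.0
        est.set_params(lambda1=0.2)
        assert est.lambda1 == 0.2


class TestPCAND:
    def test_single_iteration_reduces_to_pc(self, small_normalized):
        Wpc = pc_network(small_normalized)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est = PCAND(max_outer_iter=1).fit(small_normalized)
        assert np.abs(est.weights_ - Wpc).max() < 1e-6

    def test_scalar_omega_scales_weights(self, small_normalized):
        """With omega = c*I the correlation step returns c * X'X."""
        c = 3.0
        Y = transform_data(small_normalized, c * np.eye(30))
        W = Y.T @ Y
        assert np.allclose(W, c * (small_normalized.T @ small_normalized))

    def test_omega_symmetric_pd_along_iterations(self, small_normalized):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est = PCAND(prior="wishart", max_outer_iter=10).fit(small_normalized)
        assert np.allclose(est.omega_, est.omega_.T, atol=1e-8)
        assert np.linalg.eigvalsh(est.omega_).min() > 0
        assert np.allclose(est.weights_, est.weights_.T)


class TestJointObjective:
    def test_known_value_l1(self, small_normalized):
        X = small_normalized
        T, N = X.shape
        val = joint_objective(
            X, np.zeros((N, N)), np.eye(T), prior="l1", lambda1=0.3, lambda2=0.7
        )
        # ||X||_F^2 = N for unit-norm columns; logdet(I)=0; ||I||_1 = T
        assert np.isclose(val, N + 0.7 * T, atol=1e-10)

    def test_known_value_wishart(self, small_normalized):
        X = small_normalized
        T, N = X.shape
        val = joint_objective(
            X, np.zeros((N, N)), np.eye(T),
            prior="wishart", lambda1=0.3, nu=T, alpha=2.0,
        )
        assert np.isclose(val, N + 2.0 * T, atol=1e-10)

    def test_w_update_decreases_objective(self, small_normalized):
        X = small_normalized
        T, N = X.shape
        lam = 0.3
        before = joint_objective(
            X, np.zeros((N, N)), np.eye(T), prior="l1", lambda1=lam, lambda2=0.1
        )
        W = sr_network(X, lam)
        assert np.any(W != 0)
        after = joint_objective(
            X, W, np.eye(T), prior="l1", lambda1=lam, lambda2=0.1
        )
        assert after < before

    def test_non_pd_omega_rejected(self, small_normalized):
        X = small_normalized
        with pytest.raises(ValueError, match="positive definite"):
            joint_objective(
                X, np.zeros((8, 8)), -np.eye(30), prior="l1",
                lambda1=0.1, lambda2=0.1,
            )

    def test_trace_form_equivalence(self, rng):
        """tr[R' omega R] computed once equals tr[omega R R'] by cyclicity."""
        X = center_normalize(rng.standard_normal((15, 5)))
        W = rng.standard_normal((5, 5)) * 0.1
        A = rng.standard_normal((15, 15))
        omega = A @ A.T + 15 * np.eye(15)
        R = X - X @ W
        val = joint_objective(X, W, omega, prior="l1", lambda1=0.0, lambda2=0.0)
        direct = float(np.trace(omega @ R @ R.T)) - 5 * np.linalg.slogdet(omega)[1]
        assert np.isclose(val, direct, rtol=1e-10)
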