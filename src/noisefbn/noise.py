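"""Estimation of the shared temporal noise precision matrix.

The noise model assumes every ROI's representation error is drawn from
a zero-mean Gaussian with one common T x T precision matrix ``omega``.
Given the residual matrix ``R = X - X W`` (T time points x N ROIs), the
negative log-likelihood in ``omega`` is

    tr(omega @ S) - N * logdet(omega),        S = R @ R.T

which is ill-posed whenever ``S`` is singular (always, in the usual
T > N regime), so a prior is required:

- L1 prior: adds ``lambda2 * ||omega||_1`` and is solved as a graphical
  lasso on the scaled problem.
- Wishart prior with scale ``alpha^{-1} I`` and ``nu`` degrees of
  freedom: the posterior mode is available in closed form,
  ``omega = (N + nu) * inv(S + alpha * I)``.
"""

from __future__ import annotations

import warnings

import numpy as np


class SolverError(RuntimeError):
    """An iterative solver failed to converge; carries ``n_iter``."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(message)
        self.n_iter = n_iter


def _residual_gram(residual: np.ndarray) -> np.ndarray:
    R = np.asarray(residual, dtype=float)
    if R.ndim != 2:
        raise ValueError(f"residual must be 2-D (T x N), got shape {R.shape}")
    return R @ R.T


def omega_mle(residual, n_roi: int) -> np.ndarray:
    """Unregularized maximum-likelihood noise precision ``N * inv(S)``.

    Stationary point of ``tr(omega S) - N logdet(omega)``.  Only defined
    when the residual Gram matrix ``S = R R'`` is nonsingular, which
    requires at least as many ROIs as time points; mainly useful as a
    test oracle and as the ``lambda2 = 0`` limit of the L1 update.
    """
    S = _residual_gram(residual)
    T = S.shape[0]
    if n_roi < 1:
        raise ValueError("n_roi must be a positive integer")
    if np.linalg.matrix_rank(S) < T or np.linalg.cond(S) > 1e12:
        raise np.linalg.LinAlgError(
            "residual Gram matrix is singular or near-singular; the "
            "unregularized precision estimate is ill-posed -- use the L1 "
            "or Wishart prior instead"
        )
    omega = n_roi * np.linalg.inv(S)
    return (omega + omega.T) / 2.0


def graphical_lasso_admm(
    C,
    alpha: float,
    *,
    rho: float | None = None,
    max_iter: int = 10000,
    tol: float = 1e-7,
    abs_tol: float = 1e-9,
    penalize_diagonal: bool = True,
) -> tuple[np.ndarray, int]:
    """Graphical lasso by ADMM: ``min tr(C K) - logdet K + alpha ||K||_1``.

    The elementwise L1 penalty includes the diagonal by default
    (matching the classical graphical-lasso objective).  ADMM splits
    K into a log-det-smooth copy and a soft-thresholded copy; the
    smooth subproblem is solved exactly per iteration through one
    eigendecomposition, which keeps every iterate positive definite and
    makes the solver robust to singular ``C`` -- the operating regime
    here, where ``C`` comes from a low-rank residual Gram matrix.  The
    penalty parameter ``rho`` is adapted by residual balancing;
    stopping uses the usual combined absolute/relative residual bounds
    (``tol`` is the relative part).

    Returns the (symmetric, positive definite) solution and the number
    of ADMM iterations used.

    Raises
    ------
    SolverError
        If primal/dual residuals have not met the tolerance after
        ``max_iter`` iterations.
    """
    C = np.asarray(C, dtype=float)
    T = C.shape[0]
    if C.shape != (T, T):
        raise ValueError(f"covariance must be square, got {C.shape}")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if rho is None:
        rho = max(float(np.mean(np.diag(C))), 1e-3)
    Z = np.eye(T)
    U = np.zeros((T, T))
    for it in range(1, max_iter + 1):
        lam, Q = np.linalg.eigh(rho * (Z - U) - C)
        om = (lam + np.sqrt(lam**2 + 4.0 * rho)) / (2.0 * rho)
        K = (Q * om) @ Q.T
        Z_old = Z
        A = K + U
        Z = np.sign(A) * np.maximum(np.abs(A) - alpha / rho, 0.0)
        if not penalize_diagonal:
            np.fill_diagonal(Z, np.diag(A))
        U += K - Z
        r_primal = np.linalg.norm(K - Z)
        r_dual = rho * np.linalg.norm(Z - Z_old)
        eps_pri = T * abs_tol + tol * max(np.linalg.norm(K), np.linalg.norm(Z))
        eps_dual = T * abs_tol + tol * rho * np.linalg.norm(U)
        if r_primal < eps_pri and r_dual < eps_dual:
            return (K + K.T) / 2.0, it
        # residual balancing keeps primal and dual progress comparable
        if r_primal > 10.0 * r_dual:
            rho *= 2.0
            U /= 2.0
        elif r_dual > 10.0 * r_primal:
            rho /= 2.0
            U *= 2.0
    raise SolverError(
        f"graphical lasso (ADMM) did not converge in {max_iter} iterations "
        f"(primal residual {r_primal:.2e}, dual {r_dual:.2e})",
        max_iter,
    )


def omega_update_l1(
    residual,
    n_roi: int,
    lambda2: float,
    *,
    tol: float = 1e-7,
    max_iter: int = 10000,
) -> np.ndarray:
    """Noise precision under the sparsity (L1) prior.

    Solves ``min tr(omega S) - N logdet(omega) + lambda2 ||omega||_1``
    by dividing through by N and calling the graphical lasso with
    empirical covariance ``S / N`` and penalty ``lambda2 / N``.  The
    penalty is elementwise including the diagonal, so ``lambda2`` stays
    on the scale of the joint objective.
    """
    if lambda2 < 0:
        raise ValueError("lambda2 must be nonnegative")
    if lambda2 == 0:
        return omega_mle(residual, n_roi)
    S = _residual_gram(residual)
    T = S.shape[0]
    if np.linalg.cond(S + (lambda2 / 2.0) * np.eye(T)) > 1e14:
        ridge = 1e-8 * np.trace(S) / T
        warnings.warn(
            f"residual Gram matrix is severely ill-conditioned; adding ridge {ridge:.2e}",
            RuntimeWarning,
            stacklevel=2,
        )
        S = S + ridge * np.eye(T)
    omega, _ = graphical_lasso_admm(
        S / n_roi, lambda2 / n_roi, tol=tol, max_iter=max_iter
    )
    return omega


def omega_update_wishart(residual, n_roi: int, nu: float, alpha: float) -> np.ndarray:
    """Closed-form noise precision under the Wishart prior.

    With prior scale matrix ``alpha^{-1} I`` (an increasingly broad
    prior as ``alpha`` shrinks) and ``nu`` degrees of freedom, the
    posterior mode is

        omega = (N + nu) * inv(S + alpha * I).

    Positive definite for any residual because ``alpha > 0`` makes the
    bracket positive definite even when ``S`` is rank deficient.
    """
    S = _residual_gram(residual)
    T = S.shape[0]
    if not nu > T - 1:
        raise ValueError(
            f"Wishart degrees of freedom must exceed T - 1 = {T - 1}, got nu={nu}"
        )
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    omega = (n_roi + nu) * np.linalg.inv(S + alpha * np.eye(T))
    return (omega + omega.T) / 2.0
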