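"""Joint objectives of the alternating noise-aware estimators."""

from __future__ import annotations

import numpy as np


def joint_objective(
    X,
    W,
    omega,
    *,
    prior: str,
    lambda1: float,
    lambda2: float | None = None,
    nu: float | None = None,
    alpha: float | None = None,
) -> float:
    """Value of the joint (W, omega) objective for convergence monitoring.

    For ``prior='l1'``::

        tr[(X - XW)' omega (X - XW)] - N logdet(omega)
            + lambda1 ||W||_1 + lambda2 ||omega||_1

    For ``prior='wishart'`` (prior scale ``alpha^{-1} I``)::

        tr[omega ((X - XW)(X - XW)' + alpha I)] - (N + nu) logdet(omega)
            + lambda1 ||W||_1

    Both L1 norms are elementwise absolute sums (diagonal included for
    omega; W's diagonal is zero by construction for regression-style
    networks).

    Raises
    ------
    ValueError
        On unknown prior, inconsistent shapes, or omega not positive
        definite (log-determinant undefined).
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    omega = np.asarray(omega, dtype=float)
    T, N = X.shape
    if W.shape != (N, N):
        raise ValueError(f"W shape {W.shape} inconsistent with N={N}")
    if omega.shape != (T, T):
        raise ValueError(f"omega shape {omega.shape} inconsistent with T={T}")
    try:
        L = np.linalg.cholesky((omega + omega.T) / 2.0)
    except np.linalg.LinAlgError:
        raise ValueError(
            "omega is not positive definite: log-determinant undefined"
        ) from None
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    R = X - X @ W
    penalty_w = lambda1 * np.abs(W).sum()
    if prior == "l1":
        if lambda2 is None:
            raise ValueError("lambda2 is required for the l1 prior")
        fit = float(np.einsum("ti,ts,si->", R, omega, R))
        return fit - N * logdet + penalty_w + lambda2 * np.abs(omega).sum()
    if prior == "wishart":
        if nu is None or alpha is None:
            raise ValueError("nu and alpha are required for the wishart prior")
        fit = float(np.einsum("ti,ts,si->", R, omega, R))
        return fit + alpha * float(np.trace(omega)) - (N + nu) * logdet + penalty_w
    raise ValueError(f"unknown prior {prior!r}; expected 'l1' or 'wishart'")
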