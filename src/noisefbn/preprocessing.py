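"""Column normalization and the noise-whitening data transform."""

from __future__ import annotations

import numpy as np


def _as_time_series(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D time-series matrix, got shape {X.shape}")
    T, N = X.shape
    if T < 2 or N < 2:
        raise ValueError(
            f"need at least 2 time points and 2 ROIs, got T={T}, N={N}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("time-series matrix contains non-finite entries")
    return X


def is_normalized(X: np.ndarray, tol: float = 1e-10) -> bool:
    """True if every column has mean ~0 and unit L2 norm (within ``tol``)."""
    X = np.asarray(X, dtype=float)
    return bool(
        np.all(np.abs(X.mean(axis=0)) <= tol)
        and np.all(np.abs(np.linalg.norm(X, axis=0) - 1.0) <= tol)
    )


def center_normalize(X) -> np.ndarray:
    """Center each ROI column to zero mean and scale it to unit L2 norm.

    This is the standard pre-step for correlation- and regression-based
    network estimators: after it, ``X.T @ X`` is exactly the Pearson
    correlation matrix.  The operation is idempotent.

    Parameters
    ----------
    X : array-like of shape (T, N)
        One subject's ROI time series, time points in rows.

    Returns
    -------
    ndarray of shape (T, N)

    Raises
    ------
    ValueError
        If any column is constant (zero variance), naming its index.
    """
    X = _as_time_series(X)
    Xc = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Xc, axis=0)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(
            f"constant column(s) at index {bad.tolist()}: cannot normalize "
            "a zero-variance ROI signal"
        )
    return Xc / norms


def matrix_sqrt_spd(M, *, sym_tol: float = 1e-8, eig_tol: float = 1e-10) -> np.ndarray:
    """Unique symmetric PSD square root of a symmetric PSD matrix.

    Computed by eigendecomposition; eigenvalues in ``[-eig_tol, 0)``
    (relative to the largest eigenvalue, floor ``eig_tol`` absolute) are
    treated as round-off and clipped to zero.

    Raises
    ------
    ValueError
        If ``M`` is not symmetric within ``sym_tol`` or has an
        eigenvalue below the negative tolerance.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=sym_tol, rtol=0):
        raise ValueError("matrix is not symmetric")
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    floor = -max(eig_tol, eig_tol * abs(w[-1]))
    if w[0] < floor:
        raise ValueError(
            f"matrix is not positive semidefinite (min eigenvalue {w[0]:.3e})"
        )
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ V.T


def transform_data(X, omega) -> np.ndarray:
    """Whiten a time-series matrix by the noise precision: ``Y = sqrt(omega) @ X``.

    The transform turns the precision-weighted residual quadratic form
    into an ordinary least-squares residual, so any estimator defined on
    plain data can be run on ``Y`` to obtain its noise-aware variant.
    The result is deliberately *not* re-centered or re-normalized: the
    identity ``(x - Xw)' omega (x - Xw) = ||y - Yw||^2`` must hold
    exactly.

    Parameters
    ----------
    X : array-like of shape (T, N)
    omega : array-like of shape (T, T)
        Symmetric PSD temporal noise precision.
    """
    X = _as_time_series(X)
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (X.shape[0], X.shape[0]):
        raise ValueError(
            f"noise precision shape {omega.shape} does not match T={X.shape[0]}"
        )
    return matrix_sqrt_spd(omega) @ X
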