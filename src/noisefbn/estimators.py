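"""Network estimators: PC, SR, and their noise-depressed variants.

All estimators follow the scikit-learn convention: construct with
hyperparameters, call ``fit(X)`` with one subject's T x N time-series
matrix, read fitted attributes (``weights_``, and for the alternating
estimators ``omega_``, ``objective_trace_``, ``n_iter_``,
``converged_``).  Input columns are centered and L2-normalized
internally (the operation is idempotent, so already-normalized data
pass through unchanged).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .noise import SolverError, omega_update_l1, omega_update_wishart
from .objectives import joint_objective
from .preprocessing import center_normalize, matrix_sqrt_spd

__all__ = [
    "PearsonCorrelationNetwork",
    "SparseRepresentationNetwork",
    "SRAND",
    "PCAND",
    "pc_network",
    "sr_network",
    "srand_estimate",
    "pcand_estimate",
]


def _lasso_columns(
    Y: np.ndarray, lambda1: float, tol: float, max_iter: int
) -> np.ndarray:
    """Column-wise lasso with a structurally zero diagonal.

    Column i of W minimizes ``||y_i - Y_{-i} w||^2 + lambda1 ||w||_1``;
    ROI i is excluded from its own design matrix, so ``w_ii = 0`` holds
    by construction rather than by post-hoc zeroing.  scikit-learn's
    coordinate-descent ``Lasso`` scales its objective by ``1 / (2T)``,
    hence ``alpha = lambda1 / (2T)`` keeps ``lambda1`` on the
    unnormalized scale (where ``lambda1 >= 2`` forces W = 0 on
    unit-norm columns).
    """
    T, N = Y.shape
    if lambda1 < 0:
        raise ValueError("lambda1 must be nonnegative")
    W = np.zeros((N, N))
    if lambda1 == 0:
        # plain least squares per column; lstsq handles rank deficiency
        for i in range(N):
            idx = np.arange(N) != i
            coef, *_ = np.linalg.lstsq(Y[:, idx], Y[:, i], rcond=None)
            W[idx, i] = coef
        return W
    solver = Lasso(
        alpha=lambda1 / (2.0 * T),
        fit_intercept=False,
        tol=tol,
        max_iter=max_iter,
    )
    for i in range(N):
        idx = np.arange(N) != i
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                solver.fit(Y[:, idx], Y[:, i])
            except ConvergenceWarning as exc:
                raise SolverError(
                    f"lasso for ROI column {i} did not converge within "
                    f"{max_iter} iterations",
                    max_iter,
                ) from exc
        W[idx, i] = solver.coef_
    return W


class PearsonCorrelationNetwork(BaseEstimator):
    """Full-correlation network: ``W = X' X`` on normalized data.

    The simplest and most widely used connectivity estimator.  Produces
    a dense, symmetric matrix with unit diagonal and entries in
    [-1, 1].
    """

    def fit(self, X, y=None):
        X = center_normalize(X)
        W = X.T @ X
        self.weights_ = (W + W.T) / 2.0
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def estimator_name(self) -> str:
        return "pc"


class SparseRepresentationNetwork(BaseEstimator):
    """Sparse-representation network: per-ROI lasso on all other ROIs.

    Column i of ``weights_`` contains the L1-penalized regression
    coefficients of ROI i on the remaining ROIs, a sparse surrogate for
    partial correlation.  The matrix is asymmetric in general; the
    classification pipeline symmetrizes at feature-extraction time.

    Parameters
    ----------
    lambda1 : float
        Sparsity penalty on the unnormalized objective
        ``||X - XW||_F^2 + lambda1 ||W||_1``.  On unit-norm columns any
        ``lambda1 >= 2`` yields the all-zero network.
    lasso_tol, lasso_max_iter :
        Inner coordinate-descent control.
    """

    def __init__(
        self,
        lambda1: float = 0.3,
        *,
        lasso_tol: float = 1e-6,
        lasso_max_iter: int = 10000,
    ):
        self.lambda1 = lambda1
        self.lasso_tol = lasso_tol
        self.lasso_max_iter = lasso_max_iter

    def fit(self, X, y=None):
        X = center_normalize(X)
        self.weights_ = _lasso_columns(
            X, self.lambda1, self.lasso_tol, self.lasso_max_iter
        )
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def estimator_name(self) -> str:
        return "sr"


class _AlternatingNoiseEstimator(BaseEstimator):
    """Shared alternating loop: network step + noise-precision step.

    Subclasses provide ``_network_step(Y)`` returning W.  Each outer
    iteration whitens the data with the current noise precision
    (``Y = sqrt(omega) @ X``), re-estimates the network on Y, then
    re-estimates omega from the residual ``X - XW`` under the
    configured prior.  Iteration stops when the relative change of the
    joint objective falls below ``outer_tol``.
    """

    def __init__(
        self,
        *,
        prior: str = "l1",
        lambda2: float = 0.1,
        nu: float | None = None,
        alpha: float = 1.0,
        max_outer_iter: int = 50,
        outer_tol: float = 1e-4,
        omega_rescale: bool = False,
    ):
        self.prior = prior
        self.lambda2 = lambda2
        self.nu = nu
        self.alpha = alpha
        self.max_outer_iter = max_outer_iter
        self.outer_tol = outer_tol
        self.omega_rescale = omega_rescale

    # subclass hooks ---------------------------------------------------
    def _network_step(self, Y: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _penalty_lambda1(self) -> float:
        return 0.0

    # ------------------------------------------------------------------
    def _objective(self, X, W, omega, nu) -> float:
        kwargs = dict(prior=self.prior, lambda1=self._penalty_lambda1())
        if self.prior == "l1":
            kwargs["lambda2"] = self.lambda2
        else:
            kwargs.update(nu=nu, alpha=self.alpha)
        return joint_objective(X, W, omega, **kwargs)

    def _omega_step(self, R: np.ndarray, n_roi: int, nu: float) -> np.ndarray:
        if self.prior == "l1":
            omega = omega_update_l1(R, n_roi, self.lambda2)
        elif self.prior == "wishart":
            omega = omega_update_wishart(R, n_roi, nu, self.alpha)
        else:
            raise ValueError(
                f"unknown prior {self.prior!r}; expected 'l1' or 'wishart'"
            )
        if self.omega_rescale:
            # decouple the noise *shape* from its overall scale, which
            # otherwise multiplies the whitened data and changes the
            # effective sparsity penalty of the next network step
            omega = omega * (omega.shape[0] / np.trace(omega))
        return omega

    def fit(self, X, y=None):
        X = center_normalize(X)
        T, N = X.shape
        nu = float(self.nu) if self.nu is not None else float(T)
        if self.max_outer_iter < 1:
            raise ValueError("max_outer_iter must be >= 1")
        omega = np.eye(T)
        W = np.zeros((N, N))
        trace = [self._objective(X, W, omega, nu)]
        converged = False
        for _ in range(self.max_outer_iter):
            Y = matrix_sqrt_spd(omega) @ X
            W = self._network_step(Y)
            omega = self._omega_step(X - X @ W, N, nu)
            trace.append(self._objective(X, W, omega, nu))
            if abs(trace[-1] - trace[-2]) < self.outer_tol * abs(trace[-2]):
                converged = True
                break
        if not converged:
            warnings.warn(
                f"alternating estimation hit max_outer_iter={self.max_outer_iter} "
                "without meeting outer_tol",
                RuntimeWarning,
                stacklevel=2,
            )
        self.weights_ = W
        self.omega_ = omega
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace) - 1
        self.converged_ = converged
        self.n_features_in_ = N
        return self


class SRAND(_AlternatingNoiseEstimator):
    """Sparse representation with adaptive noise depression.

    Alternates (1) a column-wise lasso network update on the
    noise-whitened data ``Y = sqrt(omega) @ X`` and (2) an update of
    the shared temporal noise precision ``omega`` from the residual
    ``X - XW``, under either an L1 (sparsity) prior or a Wishart prior.
    Initialized at ``omega = I``, so a single iteration reproduces the
    plain SR network.

    Parameters
    ----------
    lambda1 : float
        Network sparsity penalty (same scale as
        :class:`SparseRepresentationNetwork`).
    prior : {'l1', 'wishart'}
        Noise prior.  'l1' adds ``lambda2 ||omega||_1`` and solves a
        graphical lasso per iteration; 'wishart' uses the closed-form
        posterior mode ``(N + nu) inv(S + alpha I)``.
    lambda2 : float
        L1-prior penalty on omega.
    nu : float or None
        Wishart degrees of freedom; default ``T`` (smallest integer
        exceeding T - 1).
    alpha : float
        Inverse scale of the Wishart prior matrix ``alpha^{-1} I``.
    max_outer_iter, outer_tol :
        Outer-loop control (relative change of the joint objective).
    omega_rescale : bool
        If True, rescale omega to trace T after each update.  The raw
        updates carry an overall scale (about ``N / lambda2`` or
        ``N + nu``) that multiplies Y and therefore shrinks the
        effective ``lambda1`` of the next network step; rescaling keeps
        the noise *shape* while pinning the scale to that of the
        identity initialization.  Off by default (the raw update is the
        literal objective's).
    lasso_tol, lasso_max_iter :
        Inner lasso control.
    """

    def __init__(
        self,
        lambda1: float = 0.3,
        *,
        prior: str = "l1",
        lambda2: float = 0.1,
        nu: float | None = None,
        alpha: float = 1.0,
        max_outer_iter: int = 50,
        outer_tol: float = 1e-4,
        omega_rescale: bool = False,
        lasso_tol: float = 1e-6,
        lasso_max_iter: int = 10000,
    ):
        super().__init__(
            prior=prior,
            lambda2=lambda2,
            nu=nu,
            alpha=alpha,
            max_outer_iter=max_outer_iter,
            outer_tol=outer_tol,
            omega_rescale=omega_rescale,
        )
        self.lambda1 = lambda1
        self.lasso_tol = lasso_tol
        self.lasso_max_iter = lasso_max_iter

    def _network_step(self, Y: np.ndarray) -> np.ndarray:
        return _lasso_columns(Y, self.lambda1, self.lasso_tol, self.lasso_max_iter)

    def _penalty_lambda1(self) -> float:
        return self.lambda1

    @property
    def estimator_name(self) -> str:
        return f"srand_{self.prior}"


class PCAND(_AlternatingNoiseEstimator):
    """Pearson correlation with adaptive noise depression.

    The noise-whitening module is plug-and-play: here the network step
    is simply ``W = Y' Y`` on the whitened data, and the noise
    precision is re-estimated from the residual ``X - XW`` under the
    configured prior (Wishart by default, matching the usual pairing).
    There is no sparsity penalty; the joint objective used for the
    stopping rule is the noise model's likelihood term alone, and is
    not guaranteed to decrease monotonically because the correlation
    step is not its exact minimizer.
    """

    def __init__(
        self,
        *,
        prior: str = "wishart",
        lambda2: float = 0.1,
        nu: float | None = None,
        alpha: float = 1.0,
        max_outer_iter: int = 50,
        outer_tol: float = 1e-4,
        omega_rescale: bool = False,
    ):
        super().__init__(
            prior=prior,
            lambda2=lambda2,
            nu=nu,
            alpha=alpha,
            max_outer_iter=max_outer_iter,
            outer_tol=outer_tol,
            omega_rescale=omega_rescale,
        )

    def _network_step(self, Y: np.ndarray) -> np.ndarray:
        W = Y.T @ Y
        return (W + W.T) / 2.0  # numerical safeguard; symmetric by construction

    @property
    def estimator_name(self) -> str:
        return "pcand"


# thin functional wrappers --------------------------------------------------


def pc_network(X) -> np.ndarray:
    """Pearson correlation network ``X' X`` on normalized data."""
    return PearsonCorrelationNetwork().fit(X).weights_


def sr_network(X, lambda1: float, **kwargs) -> np.ndarray:
    """Sparse-representation network (column-wise lasso, zero diagonal)."""
    return SparseRepresentationNetwork(lambda1, **kwargs).fit(X).weights_


def srand_estimate(X, lambda1: float, **kwargs):
    """Fit :class:`SRAND`; returns ``(weights, omega, objective_trace)``."""
    est = SRAND(lambda1, **kwargs).fit(X)
    return est.weights_, est.omega_, est.objective_trace_


def pcand_estimate(X, **kwargs):
    """Fit :class:`PCAND`; returns ``(weights, omega)``."""
    est = PCAND(**kwargs).fit(X)
    return est.weights_, est.omega_
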