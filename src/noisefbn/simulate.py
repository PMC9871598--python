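"""Synthetic ROI time series with known network and noise ground truth.

The generator mirrors the estimators' own data model: clean signals are
drawn i.i.d. over time from a zero-mean Gaussian with a sparse ROI
precision matrix (so true connectivity is a known sparse
partial-correlation graph), then contaminated with additive noise whose
T x T temporal covariance is shared across ROIs.  AR(1) covariance
``rho^{|t-s|}`` is the default temporal noise family -- the simplest
structure whose precision is sparse (banded), matching the rationale of
the L1 noise prior; any user-supplied SPD covariance is also accepted.

Group differences for classification experiments are injected on the
precision (partial-correlation) scale: designated edges receive an
additive offset in the patient group's precision matrix, with
diagonal-boosting repair if positive definiteness is lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "ar1_covariance",
    "make_ground_truth",
    "simulate_subject",
    "simulate_cohort",
    "recovery_score",
]


@dataclass
class SyntheticConfig:
    """Generation settings.

    Defaults give a cohort shaped like a typical resting-state study
    with the 90-ROI cerebrum parcellation: T = 170 time points, 45
    patients and 47 controls (``n_controls`` defaults to
    ``n_per_group``).  The clean signal is standardized to unit
    variance per ROI, so ``noise_scale`` is the noise-to-signal
    standard-deviation ratio.
    """

    n_roi: int = 90
    n_time: int = 170
    n_per_group: int = 45
    n_controls: int | None = 47
    edge_density: float = 0.1
    ar_rho: float = 0.6
    noise_scale: float = 0.5
    effect_size: float = 1.0
    n_effect_edges: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.edge_density < 1:
            raise ValueError("edge_density must be in (0, 1)")
        if not -1 < self.ar_rho < 1:
            raise ValueError("ar_rho must be in (-1, 1)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if self.n_roi < 2 or self.n_time < 3:
            raise ValueError("need n_roi >= 2 and n_time >= 3")


@dataclass
class GroundTruth:
    """True generating quantities, for recovery scoring."""

    roi_precision: np.ndarray
    support: frozenset  # off-diagonal (i, j), i < j, of nonzero precision
    temporal_noise_cov: np.ndarray
    noise_scale: float
    group_effect: dict = field(default_factory=dict)  # (i, j) -> additive delta

    @property
    def n_roi(self) -> int:
        return self.roi_precision.shape[0]


def ar1_covariance(n_time: int, rho: float) -> np.ndarray:
    """AR(1) covariance ``rho^{|t-s|}`` (unit marginal variance)."""
    idx = np.arange(n_time)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _repair_pd(P: np.ndarray, min_eig: float = 0.05) -> np.ndarray:
    """Boost the diagonal until the smallest eigenvalue reaches ``min_eig``."""
    w = np.linalg.eigvalsh(P)
    if w[0] < min_eig:
        warnings.warn(
            f"precision matrix not sufficiently positive definite "
            f"(min eigenvalue {w[0]:.3g}); boosting diagonal",
            RuntimeWarning,
            stacklevel=3,
        )
        P = P + (min_eig - w[0]) * np.eye(P.shape[0])
    return P


def _standardize_precision(P: np.ndarray) -> np.ndarray:
    """Rescale so the implied covariance has unit diagonal.

    Keeps the sparsity pattern (congruence by a diagonal matrix) while
    making every ROI's clean signal unit-variance, as standardized BOLD
    series are.
    """
    cov = np.linalg.inv(P)
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    P = np.linalg.inv(cov)
    # zero-out round-off on structurally zero entries
    P[np.abs(P) < 1e-12] = 0.0
    return (P + P.T) / 2.0


def make_ground_truth(cfg: SyntheticConfig) -> GroundTruth:
    """Sample a sparse ROI precision, temporal noise covariance and group effect.

    Each upper-triangle pair is an edge with probability
    ``edge_density``; edge precisions get magnitude U(0.3, 0.6) with
    random sign, and the diagonal is set to ``1 + sum_j |P_ij|``
    (strict diagonal dominance, hence positive definite) before
    standardizing the implied covariance to unit variance.  The group
    effect adds ``effect_size`` (alternating sign) to
    ``n_effect_edges`` pairs currently absent from the support, so
    patients carry extra conditional dependencies that controls lack.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_roi
    P = np.zeros((N, N))
    pairs = [(i, j) for i in range(N) for j in range(i + 1, N)]
    for i, j in pairs:
        if rng.random() < cfg.edge_density:
            v = rng.uniform(0.3, 0.6) * (1 if rng.random() < 0.5 else -1)
            P[i, j] = P[j, i] = v
    np.fill_diagonal(P, 1.0 + np.abs(P).sum(axis=1))
    P = _standardize_precision(P)
    support = frozenset((i, j) for i, j in pairs if P[i, j] != 0.0)

    non_edges = [p for p in pairs if p not in support]
    rng.shuffle(non_edges)
    k = min(cfg.n_effect_edges, len(non_edges))
    group_effect = {
        pair: cfg.effect_size * (1 if idx % 2 == 0 else -1)
        for idx, pair in enumerate(non_edges[:k])
    }
    return GroundTruth(
        roi_precision=P,
        support=support,
        temporal_noise_cov=ar1_covariance(cfg.n_time, cfg.ar_rho),
        noise_scale=cfg.noise_scale,
        group_effect=group_effect,
    )


def _group_precision(gt: GroundTruth, patient: bool) -> np.ndarray:
    P = gt.roi_precision.copy()
    if patient:
        for (i, j), delta in gt.group_effect.items():
            P[i, j] += delta
            P[j, i] += delta
        P = _repair_pd(P)
    return P


def simulate_subject(
    gt: GroundTruth,
    cfg: SyntheticConfig,
    group_label: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One subject's T x N time series: clean Gaussian draw plus shared-covariance noise.

    Clean rows are i.i.d. over time from ``N(0, inv(roi_precision))``
    (patients use the effect-shifted precision).  The noise matrix is
    ``noise_scale * L @ Z`` with ``L`` the Cholesky factor of the
    temporal noise covariance and ``Z`` i.i.d. standard normal, so
    every ROI's noise column shares the same temporal covariance.  The
    returned matrix is raw (not centered/normalized).
    """
    T = gt.temporal_noise_cov.shape[0]
    N = gt.n_roi
    P = _group_precision(gt, bool(group_label))
    L_roi = np.linalg.cholesky(np.linalg.inv(P))
    clean = rng.standard_normal((T, N)) @ L_roi.T
    if gt.noise_scale > 0:
        L_t = np.linalg.cholesky(gt.temporal_noise_cov + 1e-12 * np.eye(T))
        noise = gt.noise_scale * (L_t @ rng.standard_normal((T, N)))
    else:
        noise = 0.0
    return clean + noise


def simulate_cohort(
    cfg: SyntheticConfig,
) -> tuple[list[np.ndarray], np.ndarray, GroundTruth]:
    """Patient and control groups from one ground truth.

    Returns ``(subjects, labels, ground_truth)`` with patients first
    (label 1).  Group sizes are ``cfg.n_per_group`` patients and
    ``cfg.n_controls`` controls (defaulting to ``n_per_group``).
    Fully deterministic given ``cfg.seed``.
    """
    gt = make_ground_truth(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_pat = cfg.n_per_group
    n_con = cfg.n_controls if cfg.n_controls is not None else cfg.n_per_group
    subjects, labels = [], []
    for label, count in ((1, n_pat), (0, n_con)):
        for _ in range(count):
            subjects.append(simulate_subject(gt, cfg, label, rng))
            labels.append(label)
    return subjects, np.asarray(labels), gt


def recovery_score(
    weights, gt: GroundTruth, top_k: int | None = None
) -> tuple[float, float, float]:
    """Edge-support precision/recall/F1 of an estimated network.

    The ``top_k`` largest off-diagonal entries of the symmetrized
    absolute weight matrix are the predicted edges (default
    ``top_k = |support|``), scored against the true support.
    """
    W = np.asarray(weights, dtype=float)
    N = gt.n_roi
    if W.shape != (N, N):
        raise ValueError(f"weights shape {W.shape} does not match N={N}")
    iu = np.triu_indices(N, k=1)
    if top_k is None:
        top_k = len(gt.support)
    if top_k > iu[0].size:
        raise ValueError(f"top_k={top_k} exceeds number of ROI pairs {iu[0].size}")
    mag = np.abs((W + W.T) / 2.0)[iu]
    order = np.argsort(mag, kind="stable")[::-1][:top_k]
    predicted = {(int(iu[0][o]), int(iu[1][o])) for o in order}
    true = set(gt.support)
    tp = len(predicted & true)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(true) if true else 0.0
    f1 = (
        0.0
        if tp == 0
        else 2 * precision * recall / (precision + recall)
    )
    return precision, recall, f1
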