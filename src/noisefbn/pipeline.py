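"""FBN-to-diagnosis classification pipeline.

Workflow: extract upper-triangle edge weights as features, select
discriminative edges by a two-sample t-test on the training subjects
only, fit a linear SVM, and evaluate by leave-one-out cross-validation
(LOOCV).  The network sparsity parameter is chosen per outer fold by an
inner LOOCV grid search on training accuracy.  Network estimation is
per-subject and label-free, so networks are computed once per
(subject, lambda) and cached across folds -- mathematically identical
to re-estimating inside every fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

__all__ = [
    "feature_index",
    "extract_upper_features",
    "ttest_select",
    "confusion_metrics",
    "ClassificationReport",
    "inner_param_select",
    "loocv_evaluate",
    "DEFAULT_LAMBDA_GRID",
]

#: 20 candidate sparsity values, 0.05 to 1.00 in steps of 0.05
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(
    round(0.05 * k, 2) for k in range(1, 21)
)


def feature_index(n_roi: int) -> list[tuple[int, int]]:
    """ROI pairs (i, j) with i < j in row-major order."""
    return [(i, j) for i in range(n_roi) for j in range(i + 1, n_roi)]


def extract_upper_features(weights) -> np.ndarray:
    """Upper-triangle edge weights of a (symmetrized) network matrix.

    Asymmetric regression-style networks are symmetrized as
    ``(W + W') / 2`` first.  For N ROIs the result has length
    N (N - 1) / 2 (4005 for the standard 90-ROI cerebrum parcellation),
    ordered row-major to match :func:`feature_index`.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"network matrix must be square, got shape {W.shape}")
    W = (W + W.T) / 2.0
    iu = np.triu_indices(W.shape[0], k=1)
    return W[iu]


def features_to_network(features, n_roi: int) -> np.ndarray:
    """Inverse of :func:`extract_upper_features` (zero diagonal)."""
    features = np.asarray(features, dtype=float)
    W = np.zeros((n_roi, n_roi))
    iu = np.triu_indices(n_roi, k=1)
    if features.shape != iu[0].shape:
        raise ValueError(
            f"expected {iu[0].size} features for {n_roi} ROIs, got {features.size}"
        )
    W[iu] = features
    return W + W.T


def ttest_select(
    features,
    labels,
    p_threshold: float = 0.01,
    *,
    equal_var: bool = True,
    fallback_k: int = 10,
) -> np.ndarray:
    """Two-sample t-test feature selection.

    Runs an independent two-sample Student t-test (equal-variance by
    default; set ``equal_var=False`` for Welch) per feature between the
    two label groups and keeps features with ``p < p_threshold``.
    Features with a degenerate test statistic (zero variance in both
    groups) are never selected.  If no feature passes the threshold,
    the ``fallback_k`` smallest-p features are returned so downstream
    classification always has an input.

    Returns the selected feature indices (ascending).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    g0, g1 = X[y == classes[0]], X[y == classes[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each class needs at least 2 subjects for a t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(g0, g1, axis=0, equal_var=equal_var)
    valid = np.isfinite(t) & np.isfinite(p)
    selected = np.flatnonzero(valid & (p < p_threshold))
    if selected.size == 0:
        order = np.argsort(np.where(valid, p, np.inf), kind="stable")
        selected = np.sort(order[: min(fallback_k, int(valid.sum()))])
    return selected


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """Accuracy, sensitivity and specificity from confusion counts.

    ACC = (TP + TN) / (TP + TN + FP + FN), SEN = TP / (TP + FN),
    SPE = TN / (TN + FP).  Patients are the positive class.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    if tp + fn == 0:
        raise ValueError("no positive subjects: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no negative subjects: specificity undefined")
    acc = (tp + tn) / (tp + tn + fp + fn)
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    return acc, sen, spe


@dataclass
class ClassificationReport:
    """LOOCV outcome: confusion counts, metrics, per-fold decisions."""

    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    spe: float
    per_fold_selected_lambda: list = field(default_factory=list)
    selected_feature_counts: list = field(default_factory=list)

    @classmethod
    def from_counts(cls, tp, fp, tn, fn, **kwargs) -> "ClassificationReport":
        acc, sen, spe = confusion_metrics(tp, fp, tn, fn)
        return cls(tp=tp, fp=fp, tn=tn, fn=fn, acc=acc, sen=sen, spe=spe, **kwargs)

    def to_json(self, **dump_kwargs) -> str:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "per_fold_selected_lambda": list(self.per_fold_selected_lambda),
            "selected_feature_counts": [
                int(c) for c in self.selected_feature_counts
            ],
        }
        return json.dumps(d, **dump_kwargs)


def _fit_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    p_threshold: float,
    svm_C: float,
    equal_var: bool,
) -> tuple[np.ndarray, int]:
    """t-test selection + linear SVM on the training block only."""
    sel = ttest_select(train_X, train_y, p_threshold, equal_var=equal_var)
    clf = SVC(kernel="linear", C=svm_C)
    clf.fit(train_X[:, sel], train_y)
    return clf.predict(np.atleast_2d(test_X)[:, sel]), sel.size


def inner_param_select(
    features_by_lambda: dict,
    labels,
    grid,
    *,
    p_threshold: float = 0.01,
    svm_C: float = 1.0,
    equal_var: bool = True,
):
    """Choose the sparsity parameter by inner LOOCV accuracy.

    ``features_by_lambda[lam]`` holds the feature matrix (subjects x
    edges) of the *training* subjects for candidate ``lam``.  For each
    candidate, every training subject is held out once, the t-test
    selection and SVM are refit on the rest, and the candidate with the
    highest inner accuracy wins; ties go to the smallest lambda.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("candidate grid must be non-empty")
    if len(grid) == 1:
        return grid[0]
    y = np.asarray(labels)
    n = y.size
    best_lam, best_acc = None, -1.0
    for lam in grid:  # grid is in ascending order by convention
        X = np.asarray(features_by_lambda[lam], dtype=float)
        correct = 0
        for k in range(n):
            mask = np.arange(n) != k
            if np.unique(y[mask]).size < 2:
                raise ValueError("a class vanished from an inner training fold")
            pred, _ = _fit_predict(
                X[mask], y[mask], X[k], p_threshold, svm_C, equal_var
            )
            correct += int(pred[0] == y[k])
        acc = correct / n
        if acc > best_acc:
            best_lam, best_acc = lam, acc
    return best_lam


def loocv_evaluate(
    subjects,
    labels,
    estimator_factory,
    *,
    grid=None,
    p_threshold: float = 0.01,
    svm_C: float = 1.0,
    equal_var: bool = True,
) -> ClassificationReport:
    """Nested leave-one-out evaluation of an FBN estimation method.

    Parameters
    ----------
    subjects : sequence of (T, N) arrays
        Per-subject ROI time series (raw; estimators normalize).
    labels : sequence of {0, 1}
        1 = patient (positive class), 0 = control.
    estimator_factory : callable
        ``estimator_factory(lam)`` returns an unfitted network
        estimator for sparsity candidate ``lam`` (``lam`` is ``None``
        when the method has no sparsity parameter).
    grid : sequence of float or None
        Sparsity candidates for the inner LOOCV; ``None`` (or an empty
        sequence) means the method is parameter-free.
    p_threshold, svm_C, equal_var :
        Feature-selection and classifier settings.

    Notes
    -----
    No information from the held-out subject enters parameter
    selection, feature selection, or classifier fitting: all of those
    see only training-fold rows.  Everything is deterministic given the
    inputs.
    """
    y = np.asarray(labels).astype(int)
    n = y.size
    if len(subjects) != n:
        raise ValueError("subjects and labels length mismatch")
    if np.unique(y).size != 2:
        raise ValueError("cohort must contain both classes")
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need at least 3 subjects per class for nested LOOCV")
    grid = list(grid) if grid else [None]

    # estimation is label-free: compute features once per (lambda, subject)
    features_by_lambda = {}
    for lam in grid:
        est = estimator_factory(lam)
        feats = [
            extract_upper_features(est.fit(np.asarray(ts, dtype=float)).weights_)
            for ts in subjects
        ]
        features_by_lambda[lam] = np.vstack(feats)

    tp = fp = tn = fn = 0
    fold_lambdas, fold_counts = [], []
    for k in range(n):
        mask = np.arange(n) != k
        if np.unique(y[mask]).size < 2:
            raise ValueError("a class vanished from a training fold")
        if len(grid) > 1:
            train_feats = {
                lam: features_by_lambda[lam][mask] for lam in grid
            }
            lam = inner_param_select(
                train_feats,
                y[mask],
                grid,
                p_threshold=p_threshold,
                svm_C=svm_C,
                equal_var=equal_var,
            )
        else:
            lam = grid[0]
        X = features_by_lambda[lam]
        pred, n_sel = _fit_predict(
            X[mask], y[mask], X[k], p_threshold, svm_C, equal_var
        )
        fold_lambdas.append(lam)
        fold_counts.append(n_sel)
        if y[k] == 1:
            tp += int(pred[0] == 1)
            fn += int(pred[0] != 1)
        else:
            tn += int(pred[0] == 0)
            fp += int(pred[0] != 0)
    return ClassificationReport.from_counts(
        tp,
        fp,
        tn,
        fn,
        per_fold_selected_lambda=fold_lambdas,
        selected_feature_counts=fold_counts,
    )
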