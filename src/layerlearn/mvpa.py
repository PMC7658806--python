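"""Multivoxel pattern analysis: voxel selection, leave-one-run-out linear
classification, shuffled-label nulls, improvement indices, and the
correlation-based pattern analysis.

Voxels are ranked by the localizer-contrast t-score (left-vs-right for
visual regions, all-vs-fixation for parietal) — a statistic orthogonal to
the orientation class labels — and the top n are kept (500 for visual
areas, 200 for IPS and for any between-region comparison). A linear
maximum-margin classifier (C = 1) discriminates trained-vs-control or
untrained-vs-control orientations under leave-one-run-out
cross-validation; accuracy is averaged over folds with equal fold weight.
Learning is quantified by the decoding improvement index
``(post - pre) / pre x 100%``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.svm import SVC

from .containers import PatternDataset

logger = logging.getLogger(__name__)

#: cap applied before Fisher z so perfect correlations stay finite
FISHER_CAP = 1.0 - 1e-15


def fisher_z(r) -> np.ndarray:
    """Variance-stabilizing atanh with |r| capped just below 1."""
    return np.arctanh(np.clip(r, -FISHER_CAP, FISHER_CAP))


@dataclass
class TrainedClassifier:
    """Linear decision rule ``d(x) = w @ x + b``.

    Sign convention: positive decision values vote for the first class
    (``classes[0]``); a tie at exactly 0 is assigned to the first class.
    """

    weights: np.ndarray
    bias: float
    classes: tuple
    fold: int = -1

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision(X)
        return np.where(d >= 0, self.classes[0], self.classes[1])


@dataclass
class DecodingResult:
    """Leave-one-run-out decoding outcome for one (ROI, layer, session, task)."""

    fold_runs: list
    fold_accuracies: list
    classifiers: list
    task: tuple = ("", "")
    session: str = ""
    roi: str = ""
    layer: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def select_voxels(t_stat: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n voxels with the highest selection t-score,
    sorted by descending t. NaN t-scores rank last. If fewer than n
    voxels are available, all are returned with a warning."""
    if n <= 0:
        raise ValueError("n must be positive")
    t = np.asarray(t_stat, dtype=float)
    if n > t.size:
        logger.warning("requested %d voxels but only %d available; taking all", n, t.size)
        n = t.size
    key = np.where(np.isfinite(t), t, -np.inf)
    order = np.argsort(-key, kind="stable")
    return order[:n]


def train_linear(X: np.ndarray, y: np.ndarray, classes: tuple,
                 C: float = 1.0, fold: int = -1) -> TrainedClassifier:
    """Fit a linear maximum-margin classifier and return its hyperplane.

    The weight sign is arranged so positive decision values vote for
    ``classes[0]`` regardless of label ordering inside the solver.
    """
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    w = clf.coef_.ravel().astype(float)
    b = float(clf.intercept_[0])
    # sklearn's positive side is clf.classes_[1]
    if clf.classes_[1] != classes[0]:
        w, b = -w, -b
    return TrainedClassifier(weights=w, bias=b, classes=tuple(classes), fold=fold)


def loro_cv(dataset: PatternDataset, class_a: str, class_b: str,
            C: float = 1.0) -> DecodingResult:
    """Leave-one-run-out cross-validated two-class decoding.

    Each run serves once as the held-out test set; the classifier is
    trained on all remaining runs. A fold whose training set misses a
    class is skipped with a warning. Accuracy is the fraction of correct
    test-block predictions, averaged over folds with equal weight.
    """
    ds = dataset.task_subset(class_a, class_b)
    run_ids = np.unique(ds.runs)
    if run_ids.size < 2:
        raise ValueError("leave-one-run-out needs at least two runs")
    fold_runs, accs, clfs = [], [], []
    for fold, rid in enumerate(run_ids):
        test = ds.runs == rid
        Xtr, ytr = ds.X[~test], ds.orientation[~test]
        Xte, yte = ds.X[test], ds.orientation[test]
        if len(set(ytr)) < 2 or len(yte) == 0:
            logger.warning("fold %s missing a class; skipped", rid)
            continue
        clf = train_linear(Xtr, ytr, classes=(class_a, class_b), C=C, fold=int(rid))
        acc = float(np.mean(clf.predict(Xte) == yte))
        fold_runs.append(int(rid))
        accs.append(acc)
        clfs.append(clf)
    if not accs:
        raise ValueError("no valid folds")
    return DecodingResult(fold_runs=fold_runs, fold_accuracies=accs,
                          classifiers=clfs, task=(class_a, class_b),
                          session=ds.session, roi=ds.roi, layer=ds.layer)


def shuffled_label_null(dataset: PatternDataset, class_a: str, class_b: str,
                        n_perm: int = 5000, C: float = 1.0,
                        seed: int = 0, observed: float | None = None):
    """Permutation null for the decoding accuracy.

    Training labels are shuffled within each leave-one-run-out fold
    (test labels stay intact), the full CV repeated per permutation.
    p-value uses the add-one rule: ``(1 + #{null >= observed}) / (n_perm + 1)``.
    Returns ``(null_accuracies, p)``.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; null p-values will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    ds = dataset.task_subset(class_a, class_b)
    if observed is None:
        observed = loro_cv(dataset, class_a, class_b, C=C).mean_accuracy
    run_ids = np.unique(ds.runs)
    folds = []
    for rid in run_ids:
        test = ds.runs == rid
        folds.append((ds.X[~test], ds.orientation[~test], ds.X[test], ds.orientation[test]))
    null = np.empty(n_perm)
    for p_i in range(n_perm):
        accs = []
        for Xtr, ytr, Xte, yte in folds:
            yp = rng.permutation(ytr)
            if len(set(yp)) < 2:
                continue
            clf = train_linear(Xtr, yp, classes=(class_a, class_b), C=C)
            accs.append(np.mean(clf.predict(Xte) == yte))
        null[p_i] = np.mean(accs) if accs else np.nan
    valid = null[np.isfinite(null)]
    p = (1.0 + np.sum(valid >= observed)) / (valid.size + 1.0)
    return null, float(p)


def decoding_mpi(pre_accuracy: float, post_accuracy: float) -> float:
    """Decoding improvement index ``(post - pre) / pre x 100`` (%).

    Undefined (NaN) when the pre accuracy is zero.
    """
    if pre_accuracy == 0:
        logger.warning("pre accuracy is 0; MPI undefined")
        return float("nan")
    return (post_accuracy - pre_accuracy) / pre_accuracy * 100.0


def correlation_pattern_analysis(dataset: PatternDataset, class_a: str,
                                 class_b: str) -> float:
    """Correlation-based pattern index (Fisher z, same minus different).

    Under the leave-one-run-out split, per-class voxel mean patterns are
    computed separately for the training and test halves; the Spearman
    correlation across voxels between halves is Fisher z-transformed, and
    the index is the mean over folds of z(same-orientation pairs) minus
    z(different-orientation pairs). Folds with a constant mean pattern
    (undefined correlation) are skipped.
    """
    ds = dataset.task_subset(class_a, class_b)
    run_ids = np.unique(ds.runs)
    diffs = []
    for rid in run_ids:
        test = ds.runs == rid
        zs = {}
        ok = True
        for c1 in (class_a, class_b):
            m_tr = ds.X[~test][ds.orientation[~test] == c1].mean(axis=0)
            for c2 in (class_a, class_b):
                m_te = ds.X[test][ds.orientation[test] == c2].mean(axis=0)
                if np.ptp(m_tr) == 0 or np.ptp(m_te) == 0:
                    ok = False
                    break
                rho = spearmanr(m_tr, m_te).statistic
                zs[(c1, c2)] = fisher_z(rho)
            if not ok:
                break
        if not ok:
            logger.warning("constant mean pattern in fold %s; skipped", rid)
            continue
        same = 0.5 * (zs[(class_a, class_a)] + zs[(class_b, class_b)])
        diff = 0.5 * (zs[(class_a, class_b)] + zs[(class_b, class_a)])
        diffs.append(same - diff)
    if not diffs:
        raise ValueError("no valid folds for correlation pattern analysis")
    return float(np.mean(diffs))
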