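"""One-versus-one RBF SVM with grid search, jackknife testing and metrics.

A k-class problem is decomposed into k(k-1)/2 pairwise RBF-kernel
classifiers whose votes decide the label.  Hyperparameters (C, gamma)
are picked by grid search over integer powers of two in [2^-5, 2^5]
using stratified 10-fold cross-validated accuracy; evaluation is the
jackknife (leave-one-out) test, which yields a unique result for a
fixed dataset.  Per-class sensitivity, specificity and Matthews
correlation are computed one-vs-rest from the pooled confusion matrix:

    Sp  = TN / (TN + FP)
    Sn  = TP / (TP + FN)
    OA  = sum_i TP_i / N
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

with MCC defined as 0 when its denominator vanishes.

By default the grid search runs once on the full dataset and the chosen
pair is held fixed across all jackknife folds; this mirrors the
two-stage protocol the metrics are usually reported under but is
optimistically biased.  ``nested=True`` re-selects (C, gamma) inside
every fold instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "GridSearchConfig",
    "ConfusionMatrix",
    "EvalReport",
    "fit_ovo_svm",
    "svm_ovo_fit_predict",
    "grid_search",
    "jackknife_evaluate",
    "metrics_from_confusion",
]

logger = logging.getLogger(__name__)

_DEFAULT_GRID = tuple(2.0 ** e for e in range(-5, 6))


@dataclass
class GridSearchConfig:
    """Grid-search settings: candidate C and gamma values, CV folds, seed."""

    C_values: tuple[float, ...] = _DEFAULT_GRID
    gamma_values: tuple[float, ...] = _DEFAULT_GRID
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.C_values) or any(v <= 0 for v in self.gamma_values):
            raise ValueError("C and gamma candidates must be positive")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predicted."""

    classes: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        k = len(self.classes)
        if self.matrix.shape != (k, k):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({k}, {k})")
        if (self.matrix < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    def ovr_counts(self, i: int) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, TN, FP, FN) for class index ``i``."""
        m = self.matrix
        tp = int(m[i, i])
        fn = int(m[i].sum() - tp)
        fp = int(m[:, i].sum() - tp)
        tn = int(m.sum() - tp - fn - fp)
        return tp, tn, fp, fn


@dataclass
class EvalReport:
    """Per-class Sn/Sp/MCC, overall accuracy, and the (C, gamma) used."""

    classes: tuple
    sn: np.ndarray
    sp: np.ndarray
    mcc: np.ndarray
    oa: float
    C: float | None = None
    gamma: float | None = None

    def to_rows(self) -> list[tuple]:
        rows = [(c, float(self.sn[i]), float(self.sp[i]), float(self.mcc[i]))
                for i, c in enumerate(self.classes)]
        return rows


def fit_ovo_svm(train_X, train_y, C: float, gamma: float) -> SVC:
    """Fit the one-versus-one RBF SVM (k(k-1)/2 pairwise classifiers)."""
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    clf = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
    clf.fit(np.asarray(train_X, dtype=float), train_y)
    return clf


def svm_ovo_fit_predict(train_X, train_y, test_X, C: float, gamma: float) -> np.ndarray:
    """Train on (train_X, train_y), return predicted labels for test_X."""
    clf = fit_ovo_svm(train_X, train_y, C, gamma)
    return clf.predict(np.asarray(test_X, dtype=float))


def _effective_folds(y: np.ndarray, requested: int) -> int:
    _, counts = np.unique(y, return_counts=True)
    folds = min(requested, len(y), int(counts.min()))
    folds = max(folds, 2)
    if folds < requested:
        logger.warning("reducing CV folds from %d to %d (small dataset/classes)",
                       requested, folds)
    return folds


def grid_search(X, y, config: GridSearchConfig | None = None) -> tuple[float, float]:
    """Pick the (C, gamma) pair maximizing mean stratified-CV accuracy.

    Ties break to the smallest C, then the smallest gamma.  Folds are
    stratified and seeded; the fold count is reduced (with a warning)
    when a class is too small to stratify.
    """
    config = config or GridSearchConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        logger.warning("a class has a single member; stratified CV impossible, "
                       "falling back to the smallest (C, gamma)")
        return (min(config.C_values), min(config.gamma_values))
    folds = _effective_folds(y, config.cv_folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    # folds whose training half lost a class entirely cannot be scored
    splits = [(tr, te) for tr, te in skf.split(X, y)
              if len(np.unique(y[tr])) >= 2]
    best: tuple[float, float] | None = None
    best_acc = -1.0
    for C in sorted(config.C_values):
        for gamma in sorted(config.gamma_values):
            correct = 0
            total = 0
            for tr, te in splits:
                pred = svm_ovo_fit_predict(X[tr], y[tr], X[te], C, gamma)
                correct += int((pred == y[te]).sum())
                total += len(te)
            acc = correct / total if total else 0.0
            if acc > best_acc:  # strict: earlier (smaller) pairs win ties
                best_acc = acc
                best = (C, gamma)
    logger.info("grid search: best (C=%g, gamma=%g), CV accuracy %.4f",
                best[0], best[1], best_acc)
    return best


def metrics_from_confusion(
    cm: ConfusionMatrix, C: float | None = None, gamma: float | None = None
) -> EvalReport:
    """Per-class one-vs-rest Sn/Sp/MCC and overall accuracy.

    Any metric whose denominator is zero (a class never seen, or a
    degenerate predictor) is reported as 0.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    k = len(cm.classes)
    sn = np.zeros(k)
    sp = np.zeros(k)
    mcc = np.zeros(k)
    for i in range(k):
        tp, tn, fp, fn = cm.ovr_counts(i)
        sn[i] = tp / (tp + fn) if (tp + fn) else 0.0
        sp[i] = tn / (tn + fp) if (tn + fp) else 0.0
        denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
        mcc[i] = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    oa = float(np.trace(cm.matrix)) / cm.n
    return EvalReport(classes=cm.classes, sn=sn, sp=sp, mcc=mcc, oa=oa,
                      C=C, gamma=gamma)


def jackknife_evaluate(
    X, y, config: GridSearchConfig | None = None, nested: bool = False
) -> tuple[ConfusionMatrix, EvalReport]:
    """Leave-one-out evaluation of the OVO RBF SVM.

    Each sample is predicted by a model trained on the other N-1.  With
    ``nested=False`` (the default two-stage protocol) the grid search
    runs once on the full dataset and its (C, gamma) is reused in every
    fold; with ``nested=True`` it is re-run inside each fold.  A
    singleton class disappears from its own training fold, so its
    prediction can never be correct (logged); if only one class remains
    the fold falls back to predicting the majority class.
    """
    config = config or GridSearchConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) < 2:
        raise ValueError("need at least 2 samples for the jackknife")
    classes = tuple(np.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    class_idx = {c: i for i, c in enumerate(classes)}

    fixed = None
    if not nested:
        fixed = grid_search(X, y, config)

    singleton = {c for c in classes if (y == c).sum() == 1}
    if singleton:
        logger.warning("classes with a single member can never be predicted "
                       "correctly under the jackknife: %s", sorted(singleton))

    matrix = np.zeros((len(classes), len(classes)), dtype=int)
    mask = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        if len(np.unique(ytr)) < 2:
            labels, counts = np.unique(ytr, return_counts=True)
            pred = labels[np.argmax(counts)]
        else:
            C, gamma = fixed if fixed is not None else grid_search(Xtr, ytr, config)
            pred = svm_ovo_fit_predict(Xtr, ytr, X[i : i + 1], C, gamma)[0]
        matrix[class_idx[y[i]], class_idx[pred]] += 1
        mask[i] = True

    cm = ConfusionMatrix(classes=classes, matrix=matrix)
    C, gamma = fixed if fixed is not None else (None, None)
    report = metrics_from_confusion(cm, C=C, gamma=gamma)
    logger.info("jackknife OA = %.4f over %d samples, %d classes",
                report.oa, cm.n, len(classes))
    return cm, report
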