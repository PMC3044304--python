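"""SVM training and cross-validated evaluation.

The classifier is an RBF-kernel support vector machine whose two
hyper-parameters, the kernel width gamma and the penalty C, are drawn from
the 16-value grid {2^-7, ..., 2^8} so that each fits in a 4-bit chromosome
gene.  Fitness for the feature-subset search is the overall accuracy of
stratified five-fold cross-validation with the confusion matrix pooled over
folds (micro-average), matching ratio-style reporting such as 155/192.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: the 4-bit encodable hyper-parameter grid
PARAM_GRID = tuple(2.0**e for e in range(-7, 9))


@dataclass(frozen=True)
class SvmParams:
    gamma: float = 1.0
    cost: float = 1.0

    def __post_init__(self) -> None:
        for name, v in (("gamma", self.gamma), ("cost", self.cost)):
            if not any(np.isclose(v, g) for g in PARAM_GRID):
                raise ValueError(f"{name}={v} not on the 2^-7..2^8 grid")

    @classmethod
    def from_codes(cls, gamma_code: int, cost_code: int) -> "SvmParams":
        """Decode two 4-bit genes: parameter = 2^(code - 7)."""
        if not (0 <= gamma_code <= 15 and 0 <= cost_code <= 15):
            raise ValueError("parameter codes must be 4-bit (0..15)")
        return cls(gamma=2.0 ** (gamma_code - 7), cost=2.0 ** (cost_code - 7))


@dataclass
class MetricsReport:
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN
    folds: int = 1

    @property
    def accuracy(self) -> float:
        tp, fp, tn, fn = self.confusion
        return (tp + tn) / (tp + tn + fp + fn)

    @property
    def sensitivity(self) -> float:
        tp, _, _, fn = self.confusion
        return tp / (tp + fn) if tp + fn else 0.0

    @property
    def specificity(self) -> float:
        _, fp, tn, _ = self.confusion
        return tn / (tn + fp) if tn + fp else 0.0

    @property
    def mcc(self) -> float:
        tp, fp, tn, fn = self.confusion
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0:
            return 0.0
        return (tp * tn - fp * fn) / np.sqrt(denom)

    def as_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "tp": tp,
            "fp": fp,
            "tn": tn,
            "fn": fn,
            "folds": self.folds,
        }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


def _check_labels(y: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes present")
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} samples per class, got {counts.min()}"
        )


def make_folds(y: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, seeded fold assignment reusable across fitness calls."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cv_fitness(
    X: np.ndarray,
    y: np.ndarray,
    params: SvmParams,
    folds: int = 5,
    seed: int = 0,
    fold_splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> MetricsReport:
    """Pooled-confusion cross-validated performance of an RBF SVM.

    Deterministic given (X, y, params, folds, seed).  ``fold_splits`` lets a
    caller (the GA) reuse one fold assignment across many chromosomes so
    fitness differences reflect the feature subsets, not fold noise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_labels(y, folds)
    if fold_splits is None:
        fold_splits = make_folds(y, folds, seed)
    y_pred = np.empty_like(y)
    for train, test in fold_splits:
        clf = SVC(kernel="rbf", gamma=params.gamma, C=params.cost)
        clf.fit(X[train], y[train])
        y_pred[test] = clf.predict(X[test])
    return MetricsReport(confusion=_confusion(y, y_pred), folds=len(fold_splits))


def train_svm(X: np.ndarray, y: np.ndarray, params: SvmParams) -> SVC:
    clf = SVC(kernel="rbf", gamma=params.gamma, C=params.cost)
    clf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    return clf


def predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    params: SvmParams,
    y_test: np.ndarray | None = None,
) -> tuple[np.ndarray, MetricsReport | None]:
    """Train on the training split, predict the held-out split.

    Returns predicted labels and, when test labels are supplied, a
    :class:`MetricsReport`.  An empty test set yields an empty prediction and
    no metrics.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_test.size and X_test.shape[1] != X_train.shape[1]:
        raise ValueError("test columns do not match training columns")
    if X_test.shape[0] == 0:
        return np.array([], dtype=int), None
    clf = train_svm(X_train, y_train, params)
    y_pred = clf.predict(X_test).astype(int)
    report = None
    if y_test is not None:
        report = MetricsReport(confusion=_confusion(np.asarray(y_test, dtype=int), y_pred))
    return y_pred, report
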