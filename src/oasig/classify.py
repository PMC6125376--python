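"""RBF-kernel SVM training, leave-one-out cross-validation, and Sn/Sp/ACC/MCC.

The classifier is a C-SVM with radial basis function kernel at fixed defaults
(C = 1, gamma = 1 / number of features) with per-feature standardization from
training-set statistics (mean 0, unit SD with n−1 denominator) — the behaviour
of the classical R e1071 ``svm()`` defaults, which this package pins for
reproducibility. No class weighting is applied; with an unbalanced cohort the
Matthews correlation coefficient is the headline metric.

The positive class is ``case``. Metric conventions: a zero factor in the MCC
denominator yields MCC = 0; sensitivity (specificity) is reported as missing
(``None``) when there are no actual positives (negatives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .io import CASE, CONTROL

__all__ = [
    "SVMParams",
    "FittedSVM",
    "ConfusionMatrix",
    "PerformanceMetrics",
    "train_svm",
    "loocv_predict",
    "confusion",
    "metrics",
    "write_report",
]


@dataclass(frozen=True)
class SVMParams:
    """RBF-SVM hyperparameters. ``gamma="auto"`` resolves to 1/#features."""

    C: float = 1.0
    gamma: float | str = "auto"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if not (self.gamma == "auto" or (isinstance(self.gamma, (int, float)) and self.gamma > 0)):
            raise ValueError('gamma must be > 0 or "auto"')

    def resolve_gamma(self, n_features: int) -> float:
        return 1.0 / n_features if self.gamma == "auto" else float(self.gamma)


class FittedSVM:
    """A trained SVM plus the standardization statistics it was trained with."""

    def __init__(self, svc: SVC, mean: np.ndarray, scale: np.ndarray):
        self._svc = svc
        self._mean = mean
        self._scale = scale

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return self._svc.predict((X - self._mean) / self._scale)


def _standardization(X: np.ndarray, enabled: bool) -> tuple[np.ndarray, np.ndarray]:
    if not enabled:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    scale = np.where(scale == 0, 1.0, scale)  # constant feature: center only
    return mean, scale


def train_svm(features, labels, params: SVMParams = SVMParams()) -> FittedSVM:
    """Fit the RBF-SVM on a samples x features matrix with case/control labels.

    Deterministic for identical inputs. Raises if only one class is present.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("features must be a samples x features matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature/label length mismatch")
    present = set(np.unique(y))
    if present != {CASE, CONTROL}:
        raise ValueError(
            f"training set must contain both classes; got {sorted(present)}"
        )
    mean, scale = _standardization(X, params.standardize)
    svc = SVC(
        C=params.C,
        kernel="rbf",
        gamma=params.resolve_gamma(X.shape[1]),
        random_state=0,
    )
    svc.fit((X - mean) / scale, y)
    return FittedSVM(svc, mean, scale)


def loocv_predict(features, labels, params: SVMParams = SVMParams()) -> np.ndarray:
    """Leave-one-out cross-validated predictions, one per sample, in order.

    Each fold refits the SVM (and recomputes standardization statistics) on
    the remaining n−1 samples. Each class needs at least 2 samples so that
    every training fold retains both classes.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature/label length mismatch")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for LOOCV")
    for cls in (CASE, CONTROL):
        if int((y == cls).sum()) < 2:
            raise ValueError(f"class {cls!r} needs at least 2 samples for LOOCV")
    preds = np.empty(n, dtype=y.dtype)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = train_svm(X[mask], y[mask], params)
        preds[i] = model.predict(X[i])[0]
        mask[i] = True
    return preds


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with case (disease) as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_case(self) -> int:
        return self.tp + self.fn

    @property
    def n_control(self) -> int:
        return self.tn + self.fp


def confusion(predicted, actual) -> ConfusionMatrix:
    """Tabulate predictions against actual case/control labels."""
    p = np.asarray(predicted)
    a = np.asarray(actual)
    if p.shape != a.shape:
        raise ValueError("prediction/actual length mismatch")
    for arr, name in ((p, "predicted"), (a, "actual")):
        unknown = set(np.unique(arr)) - {CASE, CONTROL}
        if unknown:
            raise ValueError(f"unknown {name} label(s): {sorted(unknown)}")
    return ConfusionMatrix(
        tp=int(((p == CASE) & (a == CASE)).sum()),
        fn=int(((p == CONTROL) & (a == CASE)).sum()),
        fp=int(((p == CASE) & (a == CONTROL)).sum()),
        tn=int(((p == CONTROL) & (a == CONTROL)).sum()),
    )


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity, specificity, accuracy and Matthews correlation coefficient.

    ``sn``/``sp`` are ``None`` when the corresponding actual class is absent.
    """

    sn: float | None
    sp: float | None
    acc: float
    mcc: float


def metrics(cm: ConfusionMatrix) -> PerformanceMetrics:
    """Sn = TP/(TP+FN), Sp = TN/(TN+FP), ACC = (TP+TN)/n and

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

    with MCC defined as 0 when any denominator factor is zero.
    """
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    sn = cm.tp / cm.n_case if cm.n_case else None
    sp = cm.tn / cm.n_control if cm.n_control else None
    acc = (cm.tp + cm.tn) / cm.total
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
    return PerformanceMetrics(sn=sn, sp=sp, acc=acc, mcc=mcc)


def _fmt(v: float | None) -> str:
    return "NA" if v is None else f"{v:.3f}"


def write_report(cm: ConfusionMatrix, pm: PerformanceMetrics, path: str | Path) -> None:
    """Human-readable confusion-matrix + metrics report (2x2 layout)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\tActual case\tActual control\n")
        fh.write(f"Predicted case\t{cm.tp}\t{cm.fp}\n")
        fh.write(f"Predicted control\t{cm.fn}\t{cm.tn}\n")
        fh.write(
            f"Sensitivity: {_fmt(pm.sn)}\tSpecificity: {_fmt(pm.sp)}\t"
            f"Accuracy: {_fmt(pm.acc)}\tMCC: {_fmt(pm.mcc)}\n"
        )
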