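"""Confusion-matrix metrics, ROC/PR curves and the fivefold CV harness.

Metrics follow the standard confusion-matrix definitions:

    SN  = TP / (TP + FN)                      (sensitivity / recall)
    SP  = TN / (TN + FP)                      (specificity)
    PRE = TP / (TP + FP)                      (precision)
    ACC = (TP + TN) / n
    F   = 2 TP / (2 TP + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

Degenerate denominators return 0 and are flagged. AUC uses midrank handling
of ties (equivalent to the Mann-Whitney pair statistic) and AUPRC the
precision-recall step integration, both via scikit-learn. Cross-validation
is stratified, shuffled from a seed, and reports per-fold metrics with mean
and population standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import KFold, StratifiedKFold

METRIC_NAMES = ("SN", "SP", "PRE", "ACC", "F_score", "MCC", "AUC", "AUPRC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricSet:
    SN: float
    SP: float
    PRE: float
    ACC: float
    F_score: float
    MCC: float
    AUC: float = float("nan")
    AUPRC: float = float("nan")
    degenerate: set = field(default_factory=set)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts for binary labels (1 = positive class)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float, name: str, flagged: set) -> float:
    if den == 0:
        flagged.add(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts, y_true=None, scores=None) -> MetricSet:
    """Threshold metrics from confusion counts; AUC/AUPRC when scores are given.

    Degenerate denominators (e.g. precision with no predicted positives, MCC
    with a zero factor, AUC with one class) yield 0 and are listed in
    ``degenerate``.
    """
    flagged: set = set()
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    sn = _ratio(tp, tp + fn, "SN", flagged)
    sp = _ratio(tn, tn + fp, "SP", flagged)
    pre = _ratio(tp, tp + fp, "PRE", flagged)
    acc = _ratio(tp + tn, c.n, "ACC", flagged)
    f = _ratio(2 * tp, 2 * tp + fp + fn, "F_score", flagged)
    mcc_den = np.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "MCC", flagged)

    auc = auprc = float("nan")
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true required to compute AUC/AUPRC from scores")
        y_true = np.asarray(y_true, dtype=int)
        scores = np.asarray(scores, dtype=float)
        if len(np.unique(y_true)) < 2:
            flagged.update({"AUC", "AUPRC"})
            auc = auprc = 0.0
        else:
            auc = float(roc_auc_score(y_true, scores))
            auprc = float(average_precision_score(y_true, scores))
    return MetricSet(sn, sp, pre, acc, f, mcc, auc, auprc, degenerate=flagged)


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> MetricSet:
    """Full metric set from probabilistic scores at a label threshold."""
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    return metrics(confusion(y_true, y_pred), y_true=y_true, scores=scores)


# ---------------------------------------------------------------------------
# Curves


def roc_points(y_true, scores) -> pd.DataFrame:
    """ROC curve points (false-positive rate vs true-positive rate)."""
    fpr, tpr, thr = roc_curve(y_true, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def pr_points(y_true, scores) -> pd.DataFrame:
    """Precision-recall curve points from a monotone threshold sweep."""
    precision, recall, thr = precision_recall_curve(y_true, scores)
    return pd.DataFrame(
        {
            "recall": recall,
            "precision": precision,
            "threshold": np.append(thr, np.nan),
        }
    )


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVReport:
    """Per-fold metrics with mean and population std, plus fold bookkeeping."""

    folds: list[MetricSet]
    fold_assignments: np.ndarray
    seed: int

    def mean(self, name: str) -> float:
        return float(np.mean([getattr(m, name) for m in self.folds]))

    def std(self, name: str) -> float:
        # population std over folds (ddof=0)
        return float(np.std([getattr(m, name) for m in self.folds]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in METRIC_NAMES:
            row = {"metric": name, "mean": self.mean(name), "std": self.std(name)}
            row.update(
                {f"fold_{i + 1}": getattr(m, name) for i, m in enumerate(self.folds)}
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def summary(self) -> str:
        return ", ".join(
            f"{name}={self.mean(name):.3f}±{self.std(name):.3f}"
            for name in METRIC_NAMES
        )


def cross_validate(estimator, X, y, k: int = 5, seed: int = 0,
                   threshold: float = 0.5) -> CVReport:
    """Stratified k-fold cross-validation of a probabilistic classifier.

    Folds are shuffled from ``seed``; the estimator is cloned and refitted per
    fold (estimators may also be callables ``f(X_train, y_train) -> fitted``).
    Each held-out fold must contain both classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2 or k > len(y):
        raise ValueError("k must satisfy 2 <= k <= n_samples")
    counts = np.bincount(y, minlength=2)
    if k <= counts.min():
        splitter = StratifiedKFold(k, shuffle=True, random_state=seed)
    elif k == len(y):
        splitter = KFold(k)  # leave-one-out; stratification is vacuous
    else:
        raise ValueError(
            f"cannot stratify {k} folds with class counts {counts.tolist()}; "
            "use more data or smaller k"
        )
    fold_of = np.full(len(y), -1, dtype=int)
    per_fold = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                f"training fold {fold} is missing a class; use more data or smaller k"
            )
        fold_of[test_idx] = fold
        if callable(estimator) and not hasattr(estimator, "fit"):
            fitted = estimator(X[train_idx], y[train_idx])
        else:
            fitted = clone(estimator).fit(X[train_idx], y[train_idx])
        if hasattr(fitted, "predict_proba"):
            proba = fitted.predict_proba(X[test_idx])
            scores = proba[:, list(fitted.classes_).index(1)]
        else:
            scores = np.asarray(fitted.predict(X[test_idx]), dtype=float)
        per_fold.append(evaluate_predictions(y[test_idx], scores, threshold=threshold))
    return CVReport(folds=per_fold, fold_assignments=fold_of, seed=seed)
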