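"""Multi-class classifier evaluation: confusion matrix, P/R/F1, ROC, AUC.

Per-class precision, recall and F1 are computed one-vs-rest from the
confusion matrix and combined by macro (unweighted) averaging.  AUC uses the
rank statistic

    AUC = (sum of positive-sample ranks - M(M+1)/2) / (M * N)

with average ranks for ties (the Mann-Whitney treatment), which equals the
fraction of (positive, negative) pairs where the positive scores higher,
counting ties as one half.  Multi-class AUC is one-vs-rest per class on that
class's predicted probability, macro-averaged.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass
class ConfusionMatrix:
    """Square count table indexed (true class, predicted class)."""

    counts: np.ndarray
    labels: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["true\\pred"] + [str(l) for l in self.labels])
            for lab, row in zip(self.labels, self.counts):
                w.writerow([str(lab)] + [int(v) for v in row])


@dataclass
class MetricsReport:
    """All evaluation quantities for one scored dataset."""

    accuracy: float
    labels: list
    per_class_precision: dict
    per_class_recall: dict
    per_class_f1: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class_auc: dict | None = None
    macro_auc: float | None = None
    roc_points: dict | None = None   # label -> list of (fpr, tpr)
    confusion: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                str(l): {
                    "precision": self.per_class_precision[l],
                    "recall": self.per_class_recall[l],
                    "f1": self.per_class_f1[l],
                }
                for l in self.labels
            },
        }
        if self.macro_auc is not None:
            d["macro_auc"] = self.macro_auc
        if self.per_class_auc is not None:
            d["per_class_auc"] = {
                str(l): v for l, v in self.per_class_auc.items()
            }
        return d

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["metric", "class", "value"])
            w.writerow(["accuracy", "", self.accuracy])
            for name, macro, per in (
                ("precision", self.macro_precision, self.per_class_precision),
                ("recall", self.macro_recall, self.per_class_recall),
                ("f1", self.macro_f1, self.per_class_f1),
            ):
                w.writerow([name, "macro", macro])
                for l in self.labels:
                    w.writerow([name, str(l), per[l]])
            if self.per_class_auc is not None:
                w.writerow(["auc", "macro", self.macro_auc])
                for l, v in self.per_class_auc.items():
                    w.writerow(["auc", str(l), "" if v is None else v])


def confusion_matrix(y_true, y_pred, labels=None) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    index = {l: i for i, l in enumerate(labels)}
    unknown = (set(y_true.tolist()) | set(y_pred.tolist())) - set(labels)
    if unknown:
        raise ValueError(f"labels outside the known class set: {sorted(unknown)}")
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(labels))


def confusion_and_prf(y_true, y_pred, labels=None) -> MetricsReport:
    """Confusion matrix plus per-class/macro precision, recall, F1, accuracy.

    For each class, TP/FP/FN are read one-vs-rest off the confusion matrix;
    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 is their harmonic mean.
    A class never predicted (or never present) yields 0 for the undefined
    ratio.  Macro values are unweighted means over classes.
    """
    cm = confusion_matrix(y_true, y_pred, labels)
    c = cm.counts
    tp = np.diag(c).astype(float)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return MetricsReport(
        accuracy=cm.accuracy(),
        labels=cm.labels,
        per_class_precision=dict(zip(cm.labels, prec.tolist())),
        per_class_recall=dict(zip(cm.labels, rec.tolist())),
        per_class_f1=dict(zip(cm.labels, f1.tolist())),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        confusion=cm,
    )


class UndefinedMetricError(ValueError):
    """AUC/ROC is undefined because only one class is present."""


def auc_rank(scores, y_true) -> float:
    """Rank-based AUC of binary labels given scores for the positive class."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true).astype(bool)
    m = int(y.sum())
    n = int((~y).sum())
    if m == 0 or n == 0:
        raise UndefinedMetricError(
            "AUC requires at least one positive and one negative sample"
        )
    ranks = rankdata(scores, method="average")
    return float((ranks[y].sum() - m * (m + 1) / 2.0) / (m * n))


def roc_points(scores, y_true) -> list[tuple[float, float]]:
    """(FPR, TPR) staircase from (0,0) to (1,1) over all score thresholds."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true).astype(bool)
    m = int(y.sum())
    n = int((~y).sum())
    if m == 0 or n == 0:
        raise UndefinedMetricError(
            "ROC requires at least one positive and one negative sample"
        )
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(y_sorted)):
        if y_sorted[i]:
            tp += 1
        else:
            fp += 1
        # emit a vertex only between distinct thresholds
        if i == len(y_sorted) - 1 or s_sorted[i + 1] != s_sorted[i]:
            points.append((fp / n, tp / m))
    return points


def trapezoid_area(points: list[tuple[float, float]]) -> float:
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def write_roc_csv(points_by_class: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "fpr", "tpr"])
        for label, pts in points_by_class.items():
            for fpr, tpr in pts:
                w.writerow([str(label), fpr, tpr])


def multiclass_auc(proba: np.ndarray, y_true, labels=None
                   ) -> tuple[dict, float | None, dict]:
    """One-vs-rest AUC per class plus the macro mean and ROC points.

    ``proba`` is a row-stochastic (samples x classes) matrix; column order
    follows ``labels``.  A class absent from ``y_true`` gets AUC ``None`` and
    is excluded from the macro mean.
    """
    proba = np.asarray(proba, dtype=float)
    y_true = np.asarray(y_true)
    if labels is None:
        labels = sorted(set(y_true.tolist()))
    if proba.ndim != 2 or proba.shape[1] < len(labels):
        raise ValueError(
            f"probability matrix has {proba.shape[1]} columns for "
            f"{len(labels)} classes"
        )
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    aucs: dict = {}
    rocs: dict = {}
    defined = []
    for i, label in enumerate(labels):
        binary = y_true == label
        try:
            aucs[label] = auc_rank(proba[:, i], binary)
            rocs[label] = roc_points(proba[:, i], binary)
            defined.append(aucs[label])
        except UndefinedMetricError:
            import warnings

            warnings.warn(
                f"class {label!r} has no positive or no negative samples; "
                "its AUC is undefined and excluded from the macro mean"
            )
            aucs[label] = None
    macro = float(np.mean(defined)) if defined else None
    return aucs, macro, rocs


def full_report(proba: np.ndarray, y_true, labels=None) -> MetricsReport:
    """Complete report from predicted probabilities: argmax P/R/F1 plus AUC."""
    proba = np.asarray(proba, dtype=float)
    y_true = np.asarray(y_true)
    if labels is None:
        labels = sorted(set(y_true.tolist()))
    pred = np.asarray([labels[i] for i in proba.argmax(axis=1)])
    report = confusion_and_prf(y_true, pred, labels)
    aucs, macro, rocs = multiclass_auc(proba, y_true, labels)
    report.per_class_auc = aucs
    report.macro_auc = macro
    report.roc_points = rocs
    return report
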