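"""Confusion-matrix metrics and ROC/AUROC.

Positive = disease-related, negative = neutral.  The four headline metrics
are the standard confusion-count ratios

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * recall * precision / (recall + precision)
    accuracy  = (TP + TN) / (TP + FP + TN + FN)

and AUROC is computed as the rank statistic: the probability that a
randomly chosen positive outscores a randomly chosen negative, ties
counted half (equivalent to trapezoidal integration of the ROC curve).
Zero-denominator metrics are reported as 0 and flagged ``undefined``
rather than silently zeroed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exceptions import ContractError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float | None = None
    undefined: tuple = field(default_factory=tuple)

    def as_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "precision": self.precision,
             "recall": self.recall, "f1": self.f1}
        if self.auroc is not None:
            d["auroc"] = self.auroc
        if self.undefined:
            d["undefined"] = list(self.undefined)
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def to_tsv(self, path) -> None:
        d = self.as_dict()
        undef = d.pop("undefined", [])
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("metric\tvalue\tundefined\n")
            for name, value in d.items():
                fh.write(f"{name}\t{value:.6f}\t{'yes' if name in undef else 'no'}\n")


def _as_binary(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "UO":
        arr = np.array([1 if v in ("disease_related", "1", 1, True) else 0 for v in arr])
    arr = arr.astype(int)
    if not np.isin(arr, (0, 1)).all():
        raise ContractError("labels/predictions must be binary (0/1)")
    return arr


def confusion_counts(labels, predicted) -> ConfusionCounts:
    """Tally TP/FP/TN/FN; positive class = 1 = disease-related."""
    y = _as_binary(labels)
    yhat = _as_binary(predicted)
    if len(y) != len(yhat):
        raise ContractError(f"{len(y)} labels vs {len(yhat)} predictions")
    return ConfusionCounts(
        tp=int(((y == 1) & (yhat == 1)).sum()),
        fp=int(((y == 0) & (yhat == 1)).sum()),
        tn=int(((y == 0) & (yhat == 0)).sum()),
        fn=int(((y == 1) & (yhat == 0)).sum()),
    )


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """Accuracy/precision/recall/F1 from confusion counts."""
    if c.total == 0:
        raise ContractError("no evaluated records")
    undefined = []

    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall = 0.0
        undefined.append("recall")
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision = 0.0
        undefined.append("precision")
    if precision + recall > 0:
        f1 = 2 * recall * precision / (recall + precision)
    else:
        f1 = 0.0
        undefined.append("f1")
    accuracy = (c.tp + c.tn) / c.total
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         f1=f1, undefined=tuple(undefined))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * recall * precision / (recall + precision)


def roc_auc(labels, scores) -> float:
    """AUROC via the Mann–Whitney rank statistic with tie-halving."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ContractError(f"{len(y)} labels vs {len(s)} scores")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("AUROC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve_points(labels, scores) -> np.ndarray:
    """(FPR, TPR) points of the empirical ROC curve, for plotting/export."""
    from sklearn.metrics import roc_curve

    y = _as_binary(labels)
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def write_roc_points(points: np.ndarray, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")


def evaluate(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report: hard-label metrics at ``score >= threshold`` plus AUROC.

    The tie score exactly at the threshold classifies as disease-related.
    """
    s = np.asarray(scores, dtype=float)
    preds = (s >= threshold).astype(int)
    report = metrics_from_counts(confusion_counts(labels, preds))
    report.auroc = roc_auc(labels, s)
    return report
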