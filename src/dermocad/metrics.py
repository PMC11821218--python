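"""Confusion-matrix metrics, ROC/AUC and layer parameter counting.

Metrics treat melanoma (MEL) as the positive class.  Percentages are
reported rounded half-up to two decimals; raw fractions are kept
internally.  From the counts TP/FP/TN/FN:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    PRE = TP / (TP + FP)
    REC = TP / (TP + FN)
    SPE = TN / (TN + FP)
    F1  = 2 TP / (2 TP + FP + FN)

Parameter counting follows the standard per-layer formulas: a convolution
layer holds ``(kw * kh * kernels_prev + 1) * kernels`` weights, a fully
connected layer ``c * p + c``, batch normalization ``2 * features`` (the
learnable scale and shift; running statistics are not counted), and pooling
or activation layers contribute none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .netspec import NetworkSpec

POSITIVE_CLASS = "MEL"


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_labels(y_true, y_pred, positive: str = POSITIVE_CLASS) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from parallel label sequences."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p == positive)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p == positive)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p != positive)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p != positive)
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio_pct(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator; defined as 0", RuntimeWarning,
                      stacklevel=3)
        return 0.0
    return _round2(100.0 * num / den)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    return _round2(100.0 * (c.tp + c.tn) / c.total)


def precision(c: ConfusionCounts) -> float:
    return _ratio_pct(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _ratio_pct(c.tp, c.tp + c.fn, "recall")


def specificity(c: ConfusionCounts) -> float:
    return _ratio_pct(c.tn, c.tn + c.fp, "specificity")


def f1(c: ConfusionCounts) -> float:
    return _ratio_pct(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1")


def roc_auc(scores, labels, positive: str | int = 1) -> float:
    """Trapezoidal area under the TPR-vs-FPR sweep over all thresholds.

    Ties in the scores are handled by sweeping distinct score values, which
    makes the area equal to the Mann-Whitney rank statistic.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray([1 if l == positive else 0 for l in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tpr = np.r_[0.0, np.cumsum(y)[distinct] / n_pos]
    fpr = np.r_[0.0, np.cumsum(1 - y)[distinct] / n_neg]
    return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class MetricReport:
    acc: float
    pre: float
    rec: float
    spe: float
    f1: float
    auc: float | None
    counts: ConfusionCounts

    @classmethod
    def from_confusion(cls, c: ConfusionCounts, auc: float | None = None) -> "MetricReport":
        return cls(accuracy(c), precision(c), recall(c), specificity(c), f1(c), auc, c)

    def as_dict(self) -> dict:
        d = {"acc": self.acc, "pre": self.pre, "rec": self.rec,
             "spe": self.spe, "f1": self.f1, "auc": self.auc,
             "tp": self.counts.tp, "fp": self.counts.fp,
             "tn": self.counts.tn, "fn": self.counts.fn}
        return d


def count_parameters(net: NetworkSpec) -> tuple[int, list[int]]:
    """Total and per-layer learnable parameter counts of a network spec."""
    per_layer: list[int] = []
    for layer in net:
        if layer.kind == "conv":
            kh, kw = layer.kernel
            per_layer.append((kw * kh * layer.in_channels + 1) * layer.out_channels)
        elif layer.kind == "dense":
            c, p = layer.units_out, layer.units_in
            per_layer.append(c * p + c)
        elif layer.kind == "batchnorm":
            per_layer.append(2 * layer.n_features)
        elif layer.kind in ("input", "activation", "pool", "globalavgpool",
                            "flatten", "softmax"):
            per_layer.append(0)
        else:
            raise ValueError(f"unknown layer kind {layer.kind!r}")
    return sum(per_layer), per_layer


def count_kernels(net: NetworkSpec) -> int:
    """Total number of convolution kernels (filters) in the network."""
    return sum(l.out_channels for l in net.convs())
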