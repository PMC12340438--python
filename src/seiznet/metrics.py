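"""Confusion-matrix metrics and paired significance testing.

Accuracy, sensitivity (recall of the positive class), specificity (recall of
the negative class) and F1 are computed from the four confusion counts:

    Acc  = (TP + TN) / (TP + FP + TN + FN)
    Sens = TP / (TP + FN)
    Spec = TN / (TN + FP)
    F1   = 2 TP / (2 TP + FP + FN)

Which class counts as "positive" is an explicit argument (default: the
seizure class, label 1) because the convention changes Sens/Spec wholesale
on imbalanced data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = ["MetricsReport", "RunSet", "TTestResult", "evaluate", "paired_ttest"]


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_samples

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "f1": self.f1,
        }


def evaluate(predictions, labels, positive_class: int = 1) -> MetricsReport:
    """Confusion counts and the four headline metrics for binary predictions."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if predictions.shape != labels.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} predictions vs {labels.shape} labels"
        )
    pos_pred = predictions == positive_class
    pos_true = labels == positive_class
    return MetricsReport(
        tp=int(np.sum(pos_pred & pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
    )


@dataclass
class RunSet:
    """Metric values across repeated train/test cycles of one configuration."""

    values: np.ndarray
    seeds: list[int] = field(default_factory=list)
    config_hash: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("RunSet values must be a vector")


class TTestResult(NamedTuple):
    t_statistic: float
    p_value: float
    significant: bool


def paired_ttest(a, b, alpha: float = 0.05) -> TTestResult:
    """Two-sided paired t-test on per-cycle metric differences.

    Zero-variance differences are handled explicitly: all-zero differences
    give t=0, p=1; constant nonzero differences give an infinite statistic
    with p=0 (the paired design has literally no within-pair noise).
    """
    av = a.values if isinstance(a, RunSet) else np.asarray(a, dtype=np.float64)
    bv = b.values if isinstance(b, RunSet) else np.asarray(b, dtype=np.float64)
    if av.shape != bv.shape:
        raise ValueError(f"run sets differ in length: {av.shape} vs {bv.shape}")
    R = av.size
    if R < 2:
        raise ValueError("paired t-test needs at least two cycles")
    d = av - bv
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, 1.0, False)
        t = float("inf") if mean > 0 else float("-inf")
        return TTestResult(t, 0.0, True)
    t = mean / (sd / np.sqrt(R))
    p = 2.0 * stats.t.sf(abs(t), df=R - 1)
    return TTestResult(float(t), float(p), bool(p < alpha))
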