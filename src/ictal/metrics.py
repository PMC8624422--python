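"""Confusion-matrix bookkeeping and the five derived metrics.

All metrics are reported as percentages:

    Acc  = (TP + TN) / (TP + TN + FP + FN)
    Sens = TP / (TP + FN)
    Spec = TN / (TN + FP)
    Prec = TP / (TP + FP)
    F1   = 2 TP / (2 TP + FP + FN)

Multi-class K x K count matrices are reduced one-vs-rest and macro-averaged;
accuracy is then the pooled trace ratio.  A zero denominator yields 0 for
that metric with a degenerate flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "metrics_from_confusion"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary counts, or a K x K count matrix (rows = true, cols = predicted)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] < 2:
            raise ValueError("counts must be a square matrix, K >= 2")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @classmethod
    def from_binary(cls, tp: int, tn: int, fp: int, fn: int) -> "ConfusionMatrix":
        # convention: class index 1 is "positive"
        return cls(np.array([[tn, fp], [fn, tp]]))

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        classes = np.asarray(classes if classes is not None
                             else np.unique(np.concatenate([y_true, y_pred])))
        idx = {c: i for i, c in enumerate(classes.tolist())}
        k = len(classes)
        m = np.zeros((k, k), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            m[idx[t], idx[p]] += 1
        return cls(m)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) treating class i as positive."""
        c = self.counts
        tp = int(c[i, i])
        fn = int(c[i].sum() - tp)
        fp = int(c[:, i].sum() - tp)
        tn = int(c.sum() - tp - fn - fp)
        return tp, tn, fp, fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass
class MetricsReport:
    """The five metrics (percent), optionally with per-fold values."""

    acc: float
    sens: float
    spec: float
    prec: float
    f1: float
    degenerate: bool = False
    per_fold: list[dict[str, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {"acc": self.acc, "sens": self.sens, "spec": self.spec,
             "prec": self.prec, "f1": self.f1}
        if self.per_fold:
            d["per_fold"] = self.per_fold
            d["fold_mean"] = {k: float(np.mean([f[k] for f in self.per_fold]))
                              for k in ("acc", "sens", "spec", "prec", "f1")}
            d["fold_sd"] = {k: float(np.std([f[k] for f in self.per_fold]))
                            for k in ("acc", "sens", "spec", "prec", "f1")}
        return d


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def _binary_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[dict, bool]:
    acc, d0 = _safe_ratio(tp + tn, tp + tn + fp + fn)
    sens, d1 = _safe_ratio(tp, tp + fn)
    spec, d2 = _safe_ratio(tn, tn + fp)
    prec, d3 = _safe_ratio(tp, tp + fp)
    f1, d4 = _safe_ratio(2 * tp, 2 * tp + fp + fn)
    vals = {"acc": 100 * acc, "sens": 100 * sens, "spec": 100 * spec,
            "prec": 100 * prec, "f1": 100 * f1}
    return vals, any((d0, d1, d2, d3, d4))


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Five metrics from a confusion matrix (macro one-vs-rest if K > 2)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    k = cm.counts.shape[0]
    if k == 2:
        tp, tn, fp, fn = cm.one_vs_rest(1)
        vals, degenerate = _binary_metrics(tp, tn, fp, fn)
        return MetricsReport(**vals, degenerate=degenerate)
    per_class = []
    degenerate = False
    for i in range(k):
        vals, d = _binary_metrics(*cm.one_vs_rest(i))
        per_class.append(vals)
        degenerate |= d
    macro = {key: float(np.mean([v[key] for v in per_class]))
             for key in ("sens", "spec", "prec", "f1")}
    acc = 100.0 * np.trace(cm.counts) / cm.total
    return MetricsReport(acc=acc, **macro, degenerate=degenerate)
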