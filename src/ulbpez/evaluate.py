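"""Confusion-matrix evaluation: precision, recall, specificity, F1, accuracy, AUC."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics", "auc"]


@dataclass
class ConfusionMatrix:
    """k x k count table; rows are true classes, columns predictions."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square with one row per class")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=self.classes, columns=self.classes).to_csv(path)

    def __str__(self) -> str:
        return str(pd.DataFrame(self.counts, index=self.classes, columns=self.classes))


def confusion(
    y_true: Sequence, y_pred: Sequence, classes: Optional[Sequence] = None
) -> ConfusionMatrix:
    """Count table with counts[i, j] = #(true == classes[i] and pred == classes[j])."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside the declared classes: {t!r}/{p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


@dataclass
class MetricsReport:
    """Per-class and summary rates derived from one confusion matrix."""

    per_class: dict  # class -> {precision, recall, specificity, f1}
    accuracy: float
    macro: dict
    weighted: dict
    auc: Optional[float] = None
    zero_denominator: bool = False

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "per_class": {str(k): v for k, v in self.per_class.items()},
                    "accuracy": self.accuracy,
                    "macro": self.macro,
                    "weighted": self.weighted,
                    "auc": self.auc,
                    "zero_denominator": self.zero_denominator,
                },
                fh,
                indent=2,
            )


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den else (0.0, True)


def metrics(cm: ConfusionMatrix, positive=None) -> MetricsReport:
    """Precision/recall/specificity/F1 per class, overall accuracy, averages.

    Each class is treated one-vs-rest: TP its diagonal cell, FN the rest of
    its row, FP the rest of its column, TN everything else.  Zero
    denominators yield 0 and set the ``zero_denominator`` flag.  When
    ``positive`` names a class, its rates also populate the macro/weighted
    fields unchanged (the binary convention).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts
    total = cm.total
    flagged = False
    per_class: dict = {}
    support = counts.sum(axis=1)
    for i, cls in enumerate(cm.classes):
        tp = counts[i, i]
        fn = support[i] - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        precision, f1_ = _safe_div(tp, tp + fp)
        flagged |= f1_
        recall, f2_ = _safe_div(tp, tp + fn)
        flagged |= f2_
        specificity, f3_ = _safe_div(tn, tn + fp)
        flagged |= f3_
        f1, f4_ = _safe_div(2 * precision * recall, precision + recall)
        flagged |= f4_
        per_class[cls] = {
            "precision": precision,
            "recall": recall,
            "specificity": specificity,
            "f1": f1,
        }
    accuracy = float(np.trace(counts)) / total
    names = ("precision", "recall", "specificity", "f1")
    macro = {m: float(np.mean([per_class[c][m] for c in cm.classes])) for m in names}
    weights = support / total
    weighted = {
        m: float(np.sum([w * per_class[c][m] for c, w in zip(cm.classes, weights)]))
        for m in names
    }
    if positive is not None:
        if positive not in per_class:
            raise ValueError(f"unknown positive class {positive!r}")
        macro = dict(per_class[positive])
        weighted = dict(per_class[positive])
    if flagged:
        warnings.warn("zero denominator encountered; affected metrics reported as 0")
    return MetricsReport(
        per_class=per_class,
        accuracy=accuracy,
        macro=macro,
        weighted=weighted,
        zero_denominator=flagged,
    )


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2.

    ``labels`` are 0/1 (or booleans) with 1 the positive class.  Invariant
    under strictly monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
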