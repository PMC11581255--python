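"""Confusion-count bookkeeping and classification metrics.

Multi-class results are scored one-vs-rest per class and
macro-averaged.  Precision doubles as the tuning fitness: the
metaheuristic maximizes validation precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class UndefinedPrecisionError(ZeroDivisionError):
    """Raised when TP + FP = 0 (no positive predictions)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def fitness_precision(counts: ConfusionCounts) -> float:
    """Precision ``TP / (TP + FP)``, the quantity the tuner maximizes.

    Undefined when nothing was predicted positive; the caller decides
    the fallback (the pipeline maps it to fitness 0 with a warning).
    """
    if counts.tp + counts.fp == 0:
        raise UndefinedPrecisionError("no positive predictions")
    return counts.tp / (counts.tp + counts.fp)


@dataclass
class EvalReport:
    """Macro-averaged metrics plus the per-class counts behind them."""

    precision: float
    recall: float
    accuracy: float
    f_score: float
    per_class: dict[str, ConfusionCounts] = field(default_factory=dict)
    n_samples: int = 0
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "precision": self.precision, "recall": self.recall,
            "accuracy": self.accuracy, "f_score": self.f_score,
            "n_samples": self.n_samples, "seed": self.seed,
            "per_class": {k: {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn}
                          for k, c in self.per_class.items()},
            "config": self.config,
        }


def confusion_counts(predictions, labels, positive) -> ConfusionCounts:
    """One-vs-rest counts for class ``positive``."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels must have equal length")
    p_pos = pred == positive
    l_pos = lab == positive
    return ConfusionCounts(
        tp=int(np.sum(p_pos & l_pos)), fp=int(np.sum(p_pos & ~l_pos)),
        fn=int(np.sum(~p_pos & l_pos)), tn=int(np.sum(~p_pos & ~l_pos)))


def evaluate(predictions, labels, classes=None, config=None,
             seed=None) -> EvalReport:
    """Score predictions against labels.

    Per class (one-vs-rest): precision TP/(TP+FP), recall TP/(TP+FN),
    accuracy (TP+TN)/total; each macro-averaged over classes, with
    empty denominators contributing 0.  The F-score is the harmonic
    mean of macro precision and macro recall.
    """
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape or pred.ndim != 1:
        raise ValueError("predictions and labels must be equal-length 1-D")
    if pred.size == 0:
        raise ValueError("need at least one sample")
    if classes is None:
        classes = sorted(set(lab.tolist()) | set(pred.tolist()))
    per_class: dict[str, ConfusionCounts] = {}
    precs, recs, accs = [], [], []
    for cls in classes:
        c = confusion_counts(pred, lab, cls)
        per_class[str(cls)] = c
        precs.append(c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0)
        recs.append(c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0)
        accs.append((c.tp + c.tn) / c.total)
    precision = float(np.mean(precs))
    recall = float(np.mean(recs))
    accuracy = float(np.mean(accs))
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(precision=precision, recall=recall, accuracy=accuracy,
                      f_score=float(f), per_class=per_class,
                      n_samples=int(pred.size), config=config or {}, seed=seed)


def macro_precision(predictions, labels, classes=None) -> float:
    """Macro-averaged precision with the undefined case mapped to 0."""
    return evaluate(predictions, labels, classes=classes).precision
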