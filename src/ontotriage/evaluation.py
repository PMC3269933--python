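"""Evaluation metrics: confusion counts, precision/recall/F1, accuracy,
sensitivity, specificity, Matthews correlation, and interpolated AUC iP/R
over ranked predictions.

All 0/0 conventions resolve to 0 so that empty-prediction systems score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set, Tuple

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "precision_recall_f1",
    "accuracy_sens_spec",
    "mcc",
    "auc_ipr",
    "metric_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    counts: ConfusionCounts
    precision: float
    recall: float
    f1: float
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    auc_ipr: Optional[float] = None

    def as_dict(self) -> dict:
        out = {
            "tp": self.counts.tp, "fp": self.counts.fp,
            "fn": self.counts.fn, "tn": self.counts.tn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "mcc": self.mcc,
        }
        if self.auc_ipr is not None:
            out["auc_ipr"] = self.auc_ipr
        return out


def confusion(gold: Set, predicted: Set, universe: Set) -> ConfusionCounts:
    """Set-arithmetic confusion counts over a finite universe of items."""
    if not gold <= universe:
        raise ValueError(f"gold items outside universe: {sorted(gold - universe)[:5]}")
    if not predicted <= universe:
        raise ValueError(f"predicted items outside universe: {sorted(predicted - universe)[:5]}")
    tp = len(gold & predicted)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def precision_recall_f1(c: ConfusionCounts) -> Tuple[float, float, float]:
    p = _safe_div(c.tp, c.tp + c.fp)
    r = _safe_div(c.tp, c.tp + c.fn)
    f1 = _safe_div(2 * p * r, p + r)
    return p, r, f1


def accuracy_sens_spec(c: ConfusionCounts) -> Tuple[float, float, float]:
    if c.n == 0:
        raise ValueError("cannot compute metrics on an empty confusion table")
    acc = (c.tp + c.tn) / c.n
    sens = _safe_div(c.tp, c.tp + c.fn)
    spec = _safe_div(c.tn, c.tn + c.fp)
    return acc, sens, spec


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; any zero marginal factor gives 0.

    Satisfies mcc**2 * n == the 2x2 chi-square of the confusion table.
    """
    if c.n == 0:
        raise ValueError("cannot compute MCC on an empty confusion table")
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def auc_ipr(ranked: Sequence[Tuple[object, float]], gold: Set) -> float:
    """Area under the interpolated precision/recall curve.

    ``ranked`` is the full prediction list sorted by confidence descending
    (ties pre-broken deterministically). At each gold item's rank, precision
    is computed; interpolated precision at recall r is the maximum precision
    at any recall >= r; the area is the mean of the interpolated precisions
    over the |gold| recall points. Gold items absent from the ranking
    contribute precision 0.
    """
    if not gold:
        raise ValueError("gold set must be non-empty")
    confs = [conf for _, conf in ranked]
    if any(b > a for a, b in zip(confs, confs[1:])):
        raise ValueError("ranked list must be sorted by confidence descending")
    items = [item for item, _ in ranked]
    if len(items) != len(set(items)):
        raise ValueError("ranked list contains duplicate items")

    precisions: List[float] = []
    hits = 0
    for rank, item in enumerate(items, start=1):
        if item in gold:
            hits += 1
            precisions.append(hits / rank)
    # gold items never ranked: precision 0 at their recall points
    precisions.extend(0.0 for _ in range(len(gold) - hits))

    # max-interpolation from the high-recall end
    interpolated = list(precisions)
    for i in range(len(interpolated) - 2, -1, -1):
        interpolated[i] = max(interpolated[i], interpolated[i + 1])
    return sum(interpolated) / len(gold)


def metric_report(
    c: ConfusionCounts,
    ranked: Optional[Sequence[Tuple[object, float]]] = None,
    gold: Optional[Set] = None,
) -> MetricReport:
    p, r, f1 = precision_recall_f1(c)
    acc, sens, spec = accuracy_sens_spec(c)
    auc = auc_ipr(ranked, gold) if ranked is not None and gold else None
    return MetricReport(
        counts=c, precision=p, recall=r, f1=f1, accuracy=acc,
        sensitivity=sens, specificity=spec, mcc=mcc(c), auc_ipr=auc,
    )
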