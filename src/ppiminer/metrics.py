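"""Evaluation metrics and experiment harnesses.

Implements the challenge's scoring conventions: micro-averaged
precision/recall/F1 over (document, label) decisions for the multi-label
method task, and F1 / specificity / sensitivity / accuracy / Matthews
correlation / AUC iP/R for binary triage. AUC iP/R is the area under the
interpolated precision-recall curve, where interpolated precision at
recall r is the maximum precision at any recall >= r.

Also provides seeded k-fold cross-validation and a nested learning-curve
harness.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import (
    Callable,
    Dict,
    Hashable,
    Iterable,
    List,
    Mapping,
    Sequence,
    Set,
    Tuple,
    TypeVar,
)

__all__ = [
    "ConfusionCounts",
    "PRCurve",
    "multilabel_confusion",
    "prf",
    "mcc",
    "specificity",
    "sensitivity",
    "accuracy",
    "auc_ipr",
    "interpolated_pr_curve",
    "cross_validate",
    "learning_curve",
]

K = TypeVar("K", bound=Hashable)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class PRCurve:
    """Points of an interpolated precision/recall curve, recall
    non-decreasing and interpolated precision non-increasing."""

    points: List[Tuple[float, float, float]]  # (recall, precision, interpolated)


def multilabel_confusion(
    pred: Mapping[K, Set[str]], gold: Mapping[K, Set[str]]
) -> Tuple[ConfusionCounts, Dict[str, ConfusionCounts]]:
    """Micro counts pooled over all (document, label) decisions, plus a
    per-class partition. tn is not meaningful at the label level and is
    left 0."""
    if set(pred) != set(gold):
        raise ValueError("prediction and gold must cover the same documents")
    micro = ConfusionCounts()
    per_class: Dict[str, ConfusionCounts] = {}
    for doc_id in gold:
        p, g = pred[doc_id], gold[doc_id]
        for label in p | g:
            c = per_class.setdefault(label, ConfusionCounts())
            if label in p and label in g:
                micro.tp += 1
                c.tp += 1
            elif label in p:
                micro.fp += 1
                c.fp += 1
            else:
                micro.fn += 1
                c.fn += 1
    return micro, per_class


def prf(counts: ConfusionCounts) -> Tuple[float, float, float]:
    """(precision, recall, F1) with the 0-when-undefined convention."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def specificity(counts: ConfusionCounts) -> float:
    denom = counts.tn + counts.fp
    return counts.tn / denom if denom else 0.0


def sensitivity(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


def accuracy(counts: ConfusionCounts) -> float:
    total = counts.tp + counts.fp + counts.fn + counts.tn
    return (counts.tp + counts.tn) / total if total else 0.0


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when any marginal
    is empty."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def interpolated_pr_curve(
    scores: Mapping[K, float], gold: Iterable[K]
) -> PRCurve:
    """Rank all decisions by descending score (stable in input order on
    ties) and record (recall, precision) at every gold positive;
    interpolated precision at recall r is the running maximum of
    precision over recalls >= r."""
    positives = set(gold)
    n_pos = sum(1 for k in scores if k in positives)
    if n_pos == 0:
        raise ValueError("AUC iP/R requires at least one gold positive")
    ranked = sorted(scores.items(), key=lambda kv: -kv[1])
    raw: List[Tuple[float, float]] = []
    tp = 0
    for rank, (key, _score) in enumerate(ranked, 1):
        if key in positives:
            tp += 1
            raw.append((tp / n_pos, tp / rank))
    points: List[Tuple[float, float, float]] = []
    best = 0.0
    for recall, precision in reversed(raw):
        best = max(best, precision)
        points.append((recall, precision, best))
    points.reverse()
    return PRCurve(points=points)


def auc_ipr(scores: Mapping[K, float], gold: Iterable[K]) -> float:
    """Area under the interpolated precision/recall step function."""
    curve = interpolated_pr_curve(scores, gold)
    area = 0.0
    prev_recall = 0.0
    for recall, _precision, interpolated in curve.points:
        area += (recall - prev_recall) * interpolated
        prev_recall = recall
    return area


def binary_metric_row(counts: ConfusionCounts) -> Dict[str, float]:
    """The six-column schema used in the binary triage result tables."""
    _p, _r, f1 = prf(counts)
    return {
        "F1 score": f1,
        "Specificity": specificity(counts),
        "Sensitivity": sensitivity(counts),
        "Accuracy": accuracy(counts),
        "Matthews Coef": mcc(counts),
    }


# ---------------------------------------------------------------------------
# harnesses

D = TypeVar("D")
M = TypeVar("M")


def _folds(items: Sequence[D], k: int, seed: int) -> List[List[D]]:
    if k < 2:
        raise ValueError("k must be >= 2")
    order = list(items)
    random.Random(seed).shuffle(order)
    folds: List[List[D]] = [[] for _ in range(k)]
    for i, item in enumerate(order):
        folds[i % k].append(item)
    return folds


def cross_validate(
    docs: Sequence[D],
    k: int,
    seed: int,
    train_fn: Callable[[Sequence[D]], M],
    eval_fn: Callable[[M, Sequence[D]], Mapping[str, float]],
) -> Dict[str, float]:
    """Seeded k-fold cross-validation; metric dictionaries returned by
    ``eval_fn`` are averaged arithmetically across folds."""
    folds = _folds(docs, k, seed)
    sums: Dict[str, float] = {}
    for i in range(k):
        test = folds[i]
        train = [d for j, fold in enumerate(folds) if j != i for d in fold]
        if not test or not train:
            continue
        model = train_fn(train)
        for name, value in eval_fn(model, test).items():
            sums[name] = sums.get(name, 0.0) + value
    n_runs = sum(1 for f in folds if f)
    return {name: value / n_runs for name, value in sums.items()}


def learning_curve(
    docs: Sequence[D],
    fractions: Sequence[float],
    seed: int,
    train_fn: Callable[[Sequence[D]], M],
    eval_fn: Callable[[M, Sequence[D]], Mapping[str, float]],
    eval_docs: Sequence[D],
) -> Dict[float, Dict[str, float]]:
    """Train on nested seeded random subsets of ``docs`` (each larger
    fraction contains the smaller) and evaluate on a fixed held-out
    set."""
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError("fractions must lie in (0, 1]")
    order = list(docs)
    random.Random(seed).shuffle(order)
    results: Dict[float, Dict[str, float]] = {}
    for f in sorted(fractions):
        subset = order[: max(1, round(f * len(order)))]
        model = train_fn(subset)
        results[f] = dict(eval_fn(model, eval_docs))
    return results
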