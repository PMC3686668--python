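"""ROC-based decision-threshold selection for imbalanced classification.

Score-producing classifiers trained on imbalanced data tend to overlearn
the majority (pseudo-hairpin) class when cut at their default threshold.
ROC-select replaces that default: out-of-fold scores are pooled from an
internal stratified cross-validation (k1 folds), the pooled scores trace
the full ROC curve, and the threshold attaining the highest evaluation
metric — the geometric mean of sensitivity and specificity by default —
becomes the decision threshold of the final model, which is then
retrained on all the training data.

The decision rule is ``positive iff s(x) >= T``.  The score only needs to
rank instances (higher = more miRNA-like): for a random forest it is the
fraction of trees voting positive, for probabilistic classifiers the
positive-class probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core import ConfusionCounts, Metrics, metrics

#: a trainer builds a fresh scorer from (X, y); the scorer maps X -> scores
Trainer = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]

#: an evaluation functional Metrics-style: (counts) -> value to maximise
MetricFn = Callable[[ConfusionCounts], float]


def gm_metric(c: ConfusionCounts) -> float:
    """Default evaluation functional: Gm, 0 on degenerate denominators."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        return 0.0
    return metrics(c).gm


def f1_metric(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom * 100.0 if denom else 0.0


@dataclass(frozen=True)
class ScoredInstance:
    score: float
    label: int
    id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError("score must be finite")
        if self.label not in (0, 1):
            raise ValueError("label must be binary")


@dataclass(frozen=True)
class ROCPoint:
    """One achievable operating point: rule `positive iff score >= threshold`."""

    threshold: float  # +inf encodes the all-negative rule
    counts: ConfusionCounts
    se: float
    sp: float
    gm: float


@dataclass
class ThresholdedModel:
    """A trained scorer with its ROC-selected threshold and provenance."""

    scorer: Callable[[np.ndarray], np.ndarray]
    threshold: float
    k1: int
    seed: int
    metric_name: str = "gm"
    metric_value: float = float("nan")
    params: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(self.scorer(X)) >= self.threshold).astype(int)

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.scorer(X), dtype=float)


def pooled_scores(
    trainer: Trainer,
    X: np.ndarray,
    y: np.ndarray,
    k1: int = 10,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> list[ScoredInstance]:
    """Out-of-fold scores from a stratified internal CV, pooled.

    Every instance is scored exactly once, by a model trained on the other
    k1-1 folds; pooling the per-fold score sets is the curve-averaging
    strategy used here (no vertical/threshold averaging).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("pooled_scores needs both classes present")
    if counts.min() < k1:
        raise ValueError(
            f"minority class has {counts.min()} instances < k1={k1}; use smaller k1"
        )
    if ids is None:
        ids = [str(i) for i in range(len(y))]
    skf = StratifiedKFold(n_splits=k1, shuffle=True, random_state=seed)
    pooled: list[ScoredInstance] = []
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("single-class training fold; use smaller k1")
        scorer = trainer(X[train_idx], y[train_idx])
        s = np.asarray(scorer(X[test_idx]), dtype=float)
        for i, sc in zip(test_idx, s):
            pooled.append(ScoredInstance(score=float(sc), label=int(y[i]), id=ids[i]))
    return pooled


def roc_curve(scored: Sequence[ScoredInstance]) -> list[ROCPoint]:
    """All achievable operating points of threshold rules on pooled scores.

    One point per distinct score value v (rule: positive iff s >= v) in
    decreasing v order, preceded by the all-negative point (threshold
    +inf).  Tied scores move together, so the points are exactly the
    achievable confusion matrices.
    """
    labels = np.array([s.label for s in scored], dtype=int)
    scores = np.array([s.score for s in scored], dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC curve needs both classes present")
    order = np.argsort(-scores, kind="stable")
    points: list[ROCPoint] = [_roc_point(math.inf, 0, 0, n_pos, n_neg)]
    tp = fp = 0
    i = 0
    while i < len(order):
        v = scores[order[i]]
        while i < len(order) and scores[order[i]] == v:
            if labels[order[i]] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append(_roc_point(float(v), tp, fp, n_pos, n_neg))
    return points


def _roc_point(threshold: float, tp: int, fp: int, n_pos: int, n_neg: int) -> ROCPoint:
    c = ConfusionCounts(tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)
    m: Metrics = metrics(c)
    return ROCPoint(threshold=threshold, counts=c, se=m.se, sp=m.sp, gm=m.gm)


def select_threshold(
    roc: Sequence[ROCPoint], metric: MetricFn = gm_metric
) -> ROCPoint:
    """The ROC point maximising the metric.

    Ties are broken toward the highest sensitivity (the lowest threshold
    among maximisers): in miRNA screening a missed precursor costs more
    than a spurious candidate.
    """
    if not roc:
        raise ValueError("empty ROC")
    best = roc[0]
    best_val = metric(roc[0].counts)
    for p in roc[1:]:
        v = metric(p.counts)
        if (v, p.se, -p.threshold) > (best_val, best.se, -best.threshold):
            best, best_val = p, v
    return best


def stored_threshold(roc: Sequence[ROCPoint], selected: ROCPoint) -> float:
    """Robust threshold to persist: midpoint to the next higher distinct score.

    At the extremes the selected score itself (highest point) or +inf
    (all-negative rule) is kept.
    """
    if math.isinf(selected.threshold):
        return math.inf
    higher = [p.threshold for p in roc if selected.threshold < p.threshold < math.inf]
    if not higher:
        return selected.threshold
    return (selected.threshold + min(higher)) / 2.0


def roc_select_fit(
    trainer: Trainer,
    X: np.ndarray,
    y: np.ndarray,
    k1: int = 10,
    seed: int = 0,
    metric: MetricFn = gm_metric,
    metric_name: str = "gm",
    params: dict | None = None,
) -> ThresholdedModel:
    """Fit a scorer with a ROC-selected threshold.

    The threshold comes from pooled out-of-fold scores (never from scores
    of a model on its own training data); the final scorer is retrained on
    the full training set.
    """
    pooled = pooled_scores(trainer, X, y, k1=k1, seed=seed)
    curve = roc_curve(pooled)
    selected = select_threshold(curve, metric=metric)
    threshold = stored_threshold(curve, selected)
    scorer = trainer(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    return ThresholdedModel(
        scorer=scorer,
        threshold=threshold,
        k1=k1,
        seed=seed,
        metric_name=metric_name,
        metric_value=metric(selected.counts),
        params=dict(params or {}),
    )
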