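"""Grid-based classifier parameter selection via internal cross-validation.

Tuning precedes threshold selection: each grid point is scored by the mean
evaluation metric (Gm by default) over k2 stratified folds at the
classifier's *default* threshold, and the best point is handed to
ROC-select.  A flag nests ROC-select inside the tuning loop for users who
accept the extra cost of k1 inner folds per grid point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .core import confusion
from .roc_select import MetricFn, Trainer, gm_metric, roc_select_fit

#: builds a trainer from one grid point's parameter mapping
TrainerFactory = Callable[[Mapping[str, object]], Trainer]

#: default random-forest tree grid: 10, 21, ..., 219 (20 points)
DEFAULT_RF_GRID = {"n_estimators": list(range(10, 220, 11))}


@dataclass(frozen=True)
class ParameterGrid:
    """Named axes of discrete parameter values; λ = product of axis sizes."""

    axes: tuple[tuple[str, tuple[object, ...]], ...]

    @classmethod
    def from_dict(cls, axes: Mapping[str, Sequence[object]]) -> "ParameterGrid":
        items = []
        for name in sorted(axes):
            values = tuple(axes[name])
            if not values:
                raise ValueError(f"empty axis {name!r}")
            if len(set(map(repr, values))) != len(values):
                raise ValueError(f"duplicate values on axis {name!r}")
            items.append((name, values))
        if not items:
            raise ValueError("grid needs at least one axis")
        return cls(axes=tuple(items))

    @property
    def size(self) -> int:
        out = 1
        for _, values in self.axes:
            out *= len(values)
        return out


def grid_points(grid: ParameterGrid) -> list[dict[str, object]]:
    """Cartesian product, axes in lexicographic name order (deterministic)."""
    names = [name for name, _ in grid.axes]
    value_lists = [values for _, values in grid.axes]
    return [dict(zip(names, combo)) for combo in itertools.product(*value_lists)]


def grid_search(
    factory: TrainerFactory,
    X: np.ndarray,
    y: np.ndarray,
    grid: ParameterGrid,
    k2: int = 5,
    seed: int = 0,
    metric: MetricFn = gm_metric,
    default_predict: Callable[[Mapping[str, object], np.ndarray, np.ndarray], Callable] | None = None,
    nest_roc_select: bool = False,
    k1: int = 10,
) -> tuple[dict[str, object], pd.DataFrame]:
    """Pick the grid point with the highest mean metric over k2 folds.

    The same stratified fold split is reused for every point, so the
    per-point table is deterministic given the seed.  Ties go to the first
    point in deterministic grid order.  ``default_predict`` maps a grid
    point plus training data to a hard 0/1 predictor (the classifier's
    default decision rule); without it, scores are cut at 0.5 — correct
    for probability- and vote-fraction-scaled scorers.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k2 < 2:
        raise ValueError("k2 must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("grid_search needs both classes present")
    if counts.min() < k2:
        raise ValueError(
            f"minority class has {counts.min()} instances < k2={k2}; use smaller k2"
        )
    skf = StratifiedKFold(n_splits=k2, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    points = grid_points(grid)
    rows = []
    best_point: dict[str, object] | None = None
    best_mean = -np.inf
    for point in points:
        fold_vals = []
        for train_idx, test_idx in splits:
            if nest_roc_select:
                model = roc_select_fit(
                    factory(point), X[train_idx], y[train_idx],
                    k1=k1, seed=seed, metric=metric,
                )
                pred = model.predict(X[test_idx])
            elif default_predict is not None:
                predictor = default_predict(point, X[train_idx], y[train_idx])
                pred = np.asarray(predictor(X[test_idx]), dtype=int)
            else:
                scorer = factory(point)(X[train_idx], y[train_idx])
                pred = (np.asarray(scorer(X[test_idx])) >= 0.5).astype(int)
            fold_vals.append(metric(confusion(pred, y[test_idx])))
        mean_val = float(np.mean(fold_vals))
        rows.append({**point, "mean_metric": mean_val})
        if mean_val > best_mean:
            best_mean = mean_val
            best_point = point
    table = pd.DataFrame(rows)
    assert best_point is not None
    return best_point, table
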