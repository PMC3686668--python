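"""Outer cross-validated evaluation and classifier comparison statistics.

The evaluation harness runs the full pipeline — parameter tuning on k2
internal folds, then ROC threshold selection on k1 internal folds, then
scoring of the held-out outer fold — inside a stratified k-fold outer
loop, and aggregates the outer-fold confusion counts before computing
SE/SP/Gm (micro-averaging; a macro flag averages per-fold metrics
instead).  Classifier comparisons across datasets use the Friedman rank
test with Nemenyi critical differences, and paired comparisons the
Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .core import ConfusionCounts, Metrics, confusion, metrics
from .roc_select import MetricFn, gm_metric, roc_select_fit
from .tuning import ParameterGrid, TrainerFactory, grid_search

# two-tailed Nemenyi critical values (studentized range / sqrt(2)),
# infinite degrees of freedom, k = 2..10 methods
NEMENYI_Q = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
           7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589,
           7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


@dataclass(frozen=True)
class CVConfig:
    """Fold counts for the nested evaluation; defaults follow the method
    (k1 = 10 threshold-selection folds, k2 = 5 tuning folds)."""

    k1: int = 10
    k2: int = 5
    k_outer: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k_outer"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")


def stratified_folds(
    labels: Sequence[int], k: int, seed: int = 0,
    ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Fold index per instance; per-fold class counts within 1 of perfect.

    With ``ids`` supplied the assignment is keyed by id (computed on
    id-sorted order), so permuting the instances permutes the assignment
    with them and aggregate results do not depend on input order.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("stratification needs both classes")
    if counts.min() < k:
        raise ValueError(
            f"minority class has {counts.min()} instances < k={k}; use smaller k"
        )
    if ids is not None:
        if len(ids) != len(y):
            raise ValueError("ids length mismatch")
        if len(set(ids)) != len(y):
            raise ValueError("ids must be unique for id-keyed stratification")
        order = np.argsort(np.asarray(ids, dtype=object), kind="stable")
    else:
        order = np.arange(len(y))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(
        skf.split(np.zeros((len(y), 1)), y[order])
    ):
        assignment[order[test_idx]] = fold
    return assignment


def evaluate_pipeline(
    factory: TrainerFactory,
    X: np.ndarray,
    y: np.ndarray,
    grid: ParameterGrid,
    cfg: CVConfig = CVConfig(),
    metric: MetricFn = gm_metric,
    tune: bool = True,
    threshold_select: bool = True,
    default_params: Mapping[str, object] | None = None,
    macro: bool = False,
    ids: Sequence[str] | None = None,
) -> tuple[Metrics, pd.DataFrame]:
    """Nested-CV estimate of pipeline performance.

    ``tune``/``threshold_select`` toggle the two selection stages: both off
    is the raw classifier, tuning only cuts scores at the default 0.5,
    both on is the full pipeline.  Leakage is asserted per fold: train and
    test index sets are disjoint, and all inner selection sees only the
    outer-training part.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    assignment = stratified_folds(y, cfg.k_outer, seed=cfg.seed, ids=ids)
    total = ConfusionCounts(0, 0, 0, 0)
    rows = []
    fold_metrics = []
    for fold in range(cfg.k_outer):
        test_mask = assignment == fold
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        assert not set(train_idx) & set(test_idx), "fold leakage"
        X_tr, y_tr = X[train_idx], y[train_idx]
        if tune:
            params, _ = grid_search(
                factory, X_tr, y_tr, grid, k2=cfg.k2, seed=cfg.seed, metric=metric
            )
        else:
            params = dict(default_params or {})
        trainer = factory(params)
        if threshold_select:
            model = roc_select_fit(
                trainer, X_tr, y_tr, k1=cfg.k1, seed=cfg.seed, metric=metric,
                params=params,
            )
            threshold = model.threshold
            pred = model.predict(X[test_idx])
        else:
            scorer = trainer(X_tr, y_tr)
            threshold = 0.5
            pred = (np.asarray(scorer(X[test_idx])) >= 0.5).astype(int)
        c = confusion(pred, y[test_idx])
        total = total + c
        m = metrics(c) if (c.tp + c.fn) and (c.tn + c.fp) else None
        fold_metrics.append(m)
        rows.append(
            {
                "fold": fold,
                "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                "se": m.se if m else np.nan,
                "sp": m.sp if m else np.nan,
                "gm": m.gm if m else np.nan,
                "threshold": threshold,
                **{f"param_{k}": v for k, v in params.items()},
            }
        )
    detail = pd.DataFrame(rows)
    if macro:
        se = float(np.nanmean(detail["se"]))
        sp = float(np.nanmean(detail["sp"]))
        agg = Metrics(se=se, sp=sp, gm=float(np.sqrt(se * sp)))
    else:
        agg = metrics(total)
    return agg, detail


@dataclass(frozen=True)
class FriedmanResult:
    avg_ranks: pd.Series  # per method, 1 = best
    statistic: float  # Friedman chi-square
    p_value: float
    cd: float  # Nemenyi critical difference at the requested alpha


def friedman_nemenyi(
    table: pd.DataFrame, alpha: float = 0.05
) -> FriedmanResult:
    """Friedman rank test over a methods x datasets metric matrix.

    Rows are methods, columns datasets, entries the metric (higher =
    better; rank 1 = best, ties get average ranks).  The Nemenyi critical
    difference is CD = q_alpha * sqrt(k(k+1)/(6N)).
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 methods and 2 datasets")
    values = table.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite metric entries")
    k, n = values.shape
    # rank within each dataset column: best (highest) metric gets rank 1
    ranks = np.apply_along_axis(lambda col: sps.rankdata(-col), 0, values)
    avg = ranks.mean(axis=1)
    chi2 = 12.0 * n / (k * (k + 1)) * (np.sum(avg**2) - k * (k + 1) ** 2 / 4.0)
    p = float(sps.chi2.sf(chi2, df=k - 1))
    try:
        q = NEMENYI_Q[round(alpha, 2)][k]
    except KeyError:
        raise ValueError(
            f"no Nemenyi critical value tabulated for alpha={alpha}, k={k}"
        ) from None
    cd = q * np.sqrt(k * (k + 1) / (6.0 * n))
    return FriedmanResult(
        avg_ranks=pd.Series(avg, index=table.index, name="avg_rank"),
        statistic=float(chi2),
        p_value=p,
        cd=float(cd),
    )


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    w_minus: float
    statistic: float  # min(w_plus, w_minus), the usual test statistic
    p_value: float
    n: int  # pairs after dropping zero differences
    exact: bool


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the p-value is exact for n <= 25 and a
    normal approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("degenerate comparison: all differences zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    exact = len(d) <= 25
    res = sps.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return WilcoxonResult(
        w_plus=w_plus,
        w_minus=w_minus,
        statistic=min(w_plus, w_minus),
        p_value=float(res.pvalue),
        n=len(d),
        exact=exact,
    )
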