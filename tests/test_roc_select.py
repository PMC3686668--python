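import math

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from premirna.classifiers import random_forest_trainer
from premirna.core import confusion
from premirna.fixtures import make_gaussian_features
from premirna.roc_select import (
    ScoredInstance,
    gm_metric,
    f1_metric,
    pooled_scores,
    roc_curve,
    roc_select_fit,
    select_threshold,
    stored_threshold,
)


def identity_trainer(X, y):
    """Scores = first feature column (the data already is a score)."""
    return lambda X_new: np.asarray(X_new)[:, 0]


def label_leak_trainer(X, y):
    lookup = {tuple(row): label for row, label in zip(np.asarray(X), y)}
    return lambda X_new: np.array([lookup[tuple(r)] for r in np.asarray(X_new)], float)


def brute_force_best_gm(scored):
    """Oracle: enumerate every cutpoint between sorted distinct scores."""
    truth = [s.label for s in scored]
    uniq = sorted({s.score for s in scored})
    cutpoints = [uniq[0] - 1.0]
    cutpoints += uniq
    cutpoints += [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]
    cutpoints += [uniq[-1] + 1.0]
    best = 0.0
    for t in cutpoints:
        pred = [int(s.score >= t) for s in scored]
        best = max(best, gm_metric(confusion(pred, truth)))
    return best


class TestPooledScores:
    def test_partition_property(self, rng):
        X = rng.normal(size=(40, 1))
        y = np.array([1] * 15 + [0] * 25)
        ids = [f"i{k}" for k in range(40)]
        pooled = pooled_scores(identity_trainer, X, y, k1=5, seed=0, ids=ids)
        assert len(pooled) == 40
        assert sorted(s.id for s in pooled) == sorted(ids)

    def test_true_label_score_is_perfectly_separable(self, rng):
        # feature column 0 equals the label, so the held-out scores are
        # the true labels themselves
        y = np.array([1] * 10 + [0] * 20)
        X = y[:, None].astype(float)
        pooled = pooled_scores(identity_trainer, X, y, k1=3, seed=0)
        curve = roc_curve(pooled)
        assert select_threshold(curve).gm == 100.0

    def test_two_gaussian_auc_matches_closed_form(self):
        # score ~ N(1,1) for positives, N(0,1) for negatives:
        # AUC = Phi(dmu / sqrt(2))
        rng = np.random.default_rng(11)
        n = 4000
        scores = np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)])
        y = np.array([1] * n + [0] * n)
        pooled = pooled_scores(identity_trainer, scores[:, None], y, k1=5, seed=0)
        auc = roc_auc_score([s.label for s in pooled], [s.score for s in pooled])
        assert auc == pytest.approx(norm.cdf(1 / math.sqrt(2)), abs=0.02)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            pooled_scores(identity_trainer, np.zeros((5, 1)), np.ones(5), k1=2)

    def test_k1_larger_than_minority_error(self):
        X = np.zeros((10, 1))
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="smaller k1"):
            pooled_scores(identity_trainer, X, y, k1=5)


class TestRocCurve:
    def test_perfect_separation(self):
        curve = roc_curve([ScoredInstance(1.0, 1), ScoredInstance(0.0, 0)])
        gms = [p.gm for p in curve]
        assert max(gms) == 100.0
        assert select_threshold(curve).threshold == 1.0

    def test_four_instance_example_matches_brute_force(self):
        scored = [
            ScoredInstance(0.9, 1), ScoredInstance(0.8, 0),
            ScoredInstance(0.7, 1), ScoredInstance(0.6, 0),
        ]
        curve = roc_curve(scored)
        assert len(curve) == 5
        best = select_threshold(curve)
        assert best.threshold == 0.7
        assert best.gm == pytest.approx(math.sqrt(100 * 50))
        assert best.gm == pytest.approx(brute_force_best_gm(scored))
        assert stored_threshold(curve, best) == pytest.approx(0.75)

    def test_all_tied_scores_two_points(self):
        scored = [ScoredInstance(0.5, label) for label in (1, 0, 1, 0, 0)]
        curve = roc_curve(scored)
        assert len(curve) == 2
        assert curve[0].counts.tp == 0 and curve[0].counts.fp == 0
        assert curve[1].counts.tp == 2 and curve[1].counts.fp == 3

    def test_monotone_tp_fp(self, rng):
        scored = [
            ScoredInstance(float(s), int(l))
            for s, l in zip(rng.normal(size=60), rng.integers(0, 2, 60))
        ]
        curve = roc_curve(scored)
        tps = [p.counts.tp for p in curve]
        fps = [p.counts.fp for p in curve]
        assert tps == sorted(tps)
        assert fps == sorted(fps)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_curve([ScoredInstance(0.5, 1)])


class TestSelectThreshold:
    def test_oracle_equivalence_small_sets(self, rng):
        """Exhaustive check: curve maximum equals brute-force cutpoint
        maximum on hundreds of random instance sets of size <= 20,
        including heavy-tie regimes."""
        for trial in range(300):
            n = int(rng.integers(2, 21))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            if trial % 3 == 0:  # force ties
                scores = rng.integers(0, 4, n).astype(float)
            else:
                scores = rng.normal(size=n)
            scored = [ScoredInstance(float(s), int(l))
                      for s, l in zip(scores, labels)]
            curve = roc_curve(scored)
            best = select_threshold(curve)
            assert best.gm == pytest.approx(brute_force_best_gm(scored), abs=1e-9)

    def test_sensitivity_only_metric_classifies_all_positive(self):
        scored = [ScoredInstance(0.9, 1), ScoredInstance(0.1, 0)]
        curve = roc_curve(scored)
        best = select_threshold(curve, metric=lambda c: c.tp / max(c.tp + c.fn, 1))
        assert best.counts.fn == 0
        assert best.counts.tn == 0  # everything called positive

    def test_gm_and_f1_optima_can_differ(self, rng):
        scored = [ScoredInstance(float(s), 1) for s in rng.normal(1.2, 1, 12)]
        scored += [ScoredInstance(float(s), 0) for s in rng.normal(0, 1, 120)]
        curve = roc_curve(scored)
        t_gm = select_threshold(curve, metric=gm_metric).threshold
        t_f1 = select_threshold(curve, metric=f1_metric).threshold
        assert t_gm != t_f1


class TestRocSelectFit:
    def test_beats_default_threshold_out_of_sample(self):
        X, y = make_gaussian_features(50, 2500, separation=1.5, seed=7)
        tr = np.concatenate([np.flatnonzero(y == c)[: len(np.flatnonzero(y == c)) // 2]
                             for c in (0, 1)])
        te = np.setdiff1d(np.arange(len(y)), tr)
        trainer = random_forest_trainer(n_estimators=60, seed=0)
        model = roc_select_fit(trainer, X[tr], y[tr], k1=5, seed=0)
        gm_selected = gm_metric(confusion(model.predict(X[te]), y[te]))
        gm_default = gm_metric(
            confusion((model.score(X[te]) >= 0.5).astype(int), y[te])
        )
        assert gm_selected > gm_default

    def test_train_set_gm_not_hurt_for_non_memorising_scorer(self):
        # with a smooth scorer (naive Bayes) the selected threshold can
        # only improve the training-set Gm over the default cut
        from premirna.classifiers import naive_bayes_factory

        X, y = make_gaussian_features(50, 2500, separation=1.5, seed=7)
        trainer = naive_bayes_factory()({})
        model = roc_select_fit(trainer, X, y, k1=10, seed=0)
        gm_selected = gm_metric(confusion(model.predict(X), y))
        gm_default = gm_metric(
            confusion((model.score(X) >= 0.5).astype(int), y)
        )
        assert gm_selected >= gm_default

    def test_refit_reproduces_threshold(self):
        X, y = make_gaussian_features(30, 300, seed=3)
        trainer = random_forest_trainer(n_estimators=40, seed=1)
        m1 = roc_select_fit(trainer, X, y, k1=5, seed=2)
        m2 = roc_select_fit(trainer, X, y, k1=5, seed=2)
        assert m1.threshold == m2.threshold

    def test_constant_score_trainer_does_not_crash(self):
        X, y = make_gaussian_features(10, 40, seed=0)
        constant = lambda X_tr, y_tr: (lambda X_new: np.full(len(X_new), 0.5))
        model = roc_select_fit(constant, X, y, k1=2, seed=0)
        pred = model.predict(X)
        assert set(pred) <= {0, 1}
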