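"""Trainer factories adapting scikit-learn classifiers to the score contract.

A *trainer* takes ``(X, y)`` and returns a scorer ``X -> s(x)`` where
higher scores mean more miRNA-like.  For the random forest the score is
the fraction of trees voting positive; for probabilistic classifiers the
positive-class probability.  Any classifier exposing ``predict_proba``
plugs in the same way.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB

from .roc_select import Trainer
from .tuning import TrainerFactory


def _proba_trainer(make_estimator: Callable[[], object]) -> Trainer:
    def trainer(X: np.ndarray, y: np.ndarray):
        est = make_estimator()
        est.fit(X, y)
        pos_col = int(np.flatnonzero(est.classes_ == 1)[0])

        def scorer(X_new: np.ndarray) -> np.ndarray:
            return est.predict_proba(np.asarray(X_new, dtype=float))[:, pos_col]

        scorer.estimator = est  # type: ignore[attr-defined]
        return scorer

    return trainer


def random_forest_factory(seed: int = 0, **fixed) -> TrainerFactory:
    """Factory mapping grid points to random-forest trainers.

    The forest's own randomness is pinned to ``seed`` so refits with the
    same data and parameters reproduce scores exactly.
    """

    def factory(params: Mapping[str, object]) -> Trainer:
        kwargs = {"n_estimators": 100, "random_state": seed, **fixed, **params}
        return _proba_trainer(lambda: RandomForestClassifier(**kwargs))

    return factory


def random_forest_trainer(
    n_estimators: int = 100, seed: int = 0, **fixed
) -> Trainer:
    return random_forest_factory(seed=seed, **fixed)({"n_estimators": n_estimators})


def naive_bayes_factory(**fixed) -> TrainerFactory:
    def factory(params: Mapping[str, object]) -> Trainer:
        return _proba_trainer(lambda: GaussianNB(**{**fixed, **params}))

    return factory


def default_predictor(trainer: Trainer):
    """The classifier's own decision rule (no threshold selection):
    a probability/vote score cut at 0.5."""

    def predict_fn(X_train: np.ndarray, y_train: np.ndarray):
        scorer = trainer(X_train, y_train)

        def predict(X_new: np.ndarray) -> np.ndarray:
            return (np.asarray(scorer(X_new)) >= 0.5).astype(int)

        return predict

    return predict_fn
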