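"""Cancerous/non-cancerous tissue gate.

A gradient-boosted decision-tree classifier (LightGBM) separates patches
with malignant cells (cellularity > 0) from benign patches (cellularity
exactly 0), optimizing binary cross-entropy.  Downstream, gate-negative
patches receive cellularity 0 and only gate-positive patches are passed to
a regressor.  Default hyperparameters: 300 trees of depth 7, feature
fraction 0.6, bagging fraction 0.8, learning rate 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lightgbm as lgb
from scipy.stats import rankdata

from .errors import InvalidInputError, InvalidTrainingSetError, UndefinedMetricError

DEFAULT_GATE_PARAMS: dict = {
    "n_estimators": 300,
    "max_depth": 7,
    "num_leaves": 127,
    "colsample_bytree": 0.6,
    "subsample": 0.8,
    "subsample_freq": 1,
    "learning_rate": 0.01,
}


def bce_loss(scores, labels) -> float:
    """Binary cross-entropy of raw ensemble outputs F against {0,1} labels.

    -sum[y log sigma(F) + (1-y) log(1 - sigma(F))], natural log, computed
    in the numerically stable log-sum-exp form.
    """
    f = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if f.shape != y.shape:
        raise InvalidInputError("scores and labels must have equal length")
    # -[y log s + (1-y) log(1-s)] = logaddexp(0, F) - y F
    return float(np.sum(np.logaddexp(0.0, f) - y * f))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the tie-corrected Mann-Whitney statistic."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape != y.shape:
        raise InvalidInputError("scores and labels must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC AUC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties as half-credit
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class GateModel:
    """Fitted cancerous-tissue gate."""

    booster: lgb.LGBMClassifier
    threshold: float = 0.5
    params: dict = field(default_factory=dict)
    seed: int = 0

    def predict_proba(self, X) -> np.ndarray:
        """Probability that each row is cancerous."""
        return self.booster.booster_.predict(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)


def train_gate(X, labels, params: dict | None = None, seed: int = 0) -> GateModel:
    """Fit the boosted-tree gate.

    ``labels`` are {0,1} (derive as cellularity > 0).  Reproducible for a
    given seed; raises on single-class input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).ravel().astype(int)
    if X.shape[0] != y.size:
        raise InvalidInputError("X and labels must have equal length")
    if np.unique(y).size < 2:
        raise InvalidTrainingSetError("gate training needs both classes")
    merged = dict(DEFAULT_GATE_PARAMS)
    if params:
        merged.update(params)
    clf = lgb.LGBMClassifier(
        objective="binary",
        random_state=seed,
        deterministic=True,
        n_jobs=1,
        verbose=-1,
        **merged,
    )
    clf.fit(X, y)
    return GateModel(booster=clf, params=merged, seed=seed)
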