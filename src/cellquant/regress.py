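"""Cellularity estimators for cancerous patches.

Four models estimate cellularity from a refined feature vector:

* ``huber_gbdt`` — boosted trees on the Huber objective (delta = 1), a
  direct regression on cellularity robust to label outliers.
* ``ranknet_gbdt`` — boosted trees trained with the pairwise RankNet
  objective: for sample pairs in *adjacent* cellularity levels, the model
  score difference is pushed through a sigmoid and fit with binary
  cross-entropy, so the ensemble learns a ranking score rather than a
  magnitude.
* ``svr`` — support vector regression, RBF kernel, C = 200,
  gamma = 1e-4, epsilon = 0 (with epsilon = 0 and squared slacks SVR
  collapses to L2-regularized regression, which is why small-gamma RBF
  behaves almost linearly).
* ``rank_svm`` — a linear max-margin ranker on adjacent-pair difference
  vectors, C = 1e8 (effectively hard margin).

Cellularity labels live on the dataset's 37-value grid and are translated
to integer ranking levels 0..36 before pair construction.  Ranking scores
are mapped back to cellularity by K-nearest-neighbor calibration (k = 30)
against the training scores, and all estimators finish with a linear
correction that matches the first two moments of the training labels,
then clipping to [0, 1].

Internally a higher ranking score always means higher cellularity; both
training and calibration use this one convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import lightgbm as lgb
import xgboost as xgb
from sklearn.svm import SVR as _SkSVR
from sklearn.svm import LinearSVC
from sklearn.exceptions import ConvergenceWarning

from .errors import (
    EmptyPairSetError,
    InvalidInputError,
    InvalidParameterError,
    InvalidTrainingSetError,
)

logger = logging.getLogger(__name__)

ESTIMATOR_KINDS = ("huber_gbdt", "ranknet_gbdt", "svr", "rank_svm")

# ---------------------------------------------------------------------------
# Level translation


def _build_grid() -> np.ndarray:
    ones = np.arange(0, 11) / 100.0          # 0, 1%, ..., 10%   -> levels 0..10
    fives = np.arange(15, 95, 5) / 100.0     # 15%, 20%, ..., 90% -> levels 11..26
    tail = np.arange(91, 101) / 100.0        # 91%, ..., 100%     -> levels 27..36
    return np.round(np.concatenate([ones, fives, tail]), 6)


@dataclass(frozen=True)
class LevelMap:
    """Bidirectional map between the cellularity grid and levels 0..36."""

    grid: np.ndarray = field(default_factory=_build_grid)

    @property
    def n_levels(self) -> int:
        return self.grid.size


DEFAULT_LEVEL_MAP = LevelMap()


def cellularity_to_level(c, level_map: LevelMap = DEFAULT_LEVEL_MAP):
    """Snap cellularity in [0,1] to the nearest grid bin (ties toward the
    lower bin) and return its integer level."""
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise InvalidInputError("cellularity must lie in [0, 1]")
    flat = np.atleast_1d(arr)
    idx = np.abs(level_map.grid[None, :] - flat[:, None]).argmin(axis=1)
    return int(idx[0]) if arr.ndim == 0 else idx.astype(int)


def level_to_cellularity(level, level_map: LevelMap = DEFAULT_LEVEL_MAP):
    arr = np.asarray(level, dtype=int)
    if np.any(arr < 0) or np.any(arr >= level_map.n_levels):
        raise InvalidInputError(
            f"level must lie in [0, {level_map.n_levels - 1}]"
        )
    out = level_map.grid[arr]
    return float(out) if np.isscalar(level) or np.ndim(level) == 0 else out


# ---------------------------------------------------------------------------
# Losses and pairwise machinery


def huber_loss(residuals, delta: float = 1.0) -> float:
    """Sum of Huber penalties: quadratic within |r| <= delta, linear beyond."""
    if delta <= 0:
        raise InvalidParameterError(f"delta must be positive, got {delta}")
    r = np.abs(np.asarray(residuals, dtype=float))
    quad = r <= delta
    return float(
        np.sum(0.5 * r[quad] ** 2) + np.sum(delta * (r[~quad] - 0.5 * delta))
    )


@dataclass(frozen=True)
class RankPair:
    """A training pair in adjacent levels; orientation 1 means the model
    score of ``index_high`` should exceed that of ``index_low``."""

    index_low: int
    index_high: int
    orientation: int = 1


def build_adjacent_pairs(levels) -> list[RankPair]:
    """All cross pairs (i, j) with level(j) = level(i) + 1."""
    lo, hi = _adjacent_pair_arrays(levels)
    return [RankPair(int(i), int(j)) for i, j in zip(lo, hi)]


def _adjacent_pair_arrays(levels) -> tuple[np.ndarray, np.ndarray]:
    levels = np.asarray(levels, dtype=int).ravel()
    if np.unique(levels).size < 2:
        raise EmptyPairSetError("all samples share one level: no adjacent pairs")
    lo_list, hi_list = [], []
    for lev in np.unique(levels):
        idx_lo = np.flatnonzero(levels == lev)
        idx_hi = np.flatnonzero(levels == lev + 1)
        if idx_lo.size and idx_hi.size:
            g_lo, g_hi = np.meshgrid(idx_lo, idx_hi, indexing="ij")
            lo_list.append(g_lo.ravel())
            hi_list.append(g_hi.ravel())
    if not lo_list:
        raise EmptyPairSetError("no occupied adjacent level pairs")
    return np.concatenate(lo_list), np.concatenate(hi_list)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def ranknet_pair_prob(f_i, f_j, k: float = 1.0):
    """Probability that sample i outranks sample j: sigmoid(k (F_i - F_j))."""
    if k <= 0:
        raise InvalidParameterError(f"sigmoid scale k must be positive, got {k}")
    return _sigmoid(k * (np.asarray(f_i, dtype=float) - np.asarray(f_j, dtype=float)))


def rank_loss(scores, pairs, k: float = 1.0) -> float:
    """Sum of pairwise binary cross-entropies over the given pairs."""
    scores = np.asarray(scores, dtype=float).ravel()
    if len(pairs) == 0:
        raise InvalidInputError("pair set is empty")
    lo = np.array([p.index_low for p in pairs])
    hi = np.array([p.index_high for p in pairs])
    tgt = np.array([p.orientation for p in pairs], dtype=float)
    z = k * (scores[hi] - scores[lo])
    # BCE(sigma(z), tgt) = logaddexp(0, z) - tgt * z
    return float(np.sum(np.logaddexp(0.0, z) - tgt * z))


# ---------------------------------------------------------------------------
# Calibration and correction


def knn_calibrate(score, train_scores, train_cells, k: int = 30):
    """Map ranking score(s) to cellularity: mean label of the k training
    samples with nearest scores (absolute difference, ties by index order)."""
    train_scores = np.asarray(train_scores, dtype=float).ravel()
    train_cells = np.asarray(train_cells, dtype=float).ravel()
    if train_scores.shape != train_cells.shape:
        raise InvalidInputError("train_scores and train_cells must align")
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if train_scores.size < k:
        logger.warning(
            "KNN calibration has %d < k=%d training points; using all",
            train_scores.size, k,
        )
        k = train_scores.size
    queries = np.atleast_1d(np.asarray(score, dtype=float))
    out = np.empty(queries.size)
    for i, q in enumerate(queries):
        order = np.argsort(np.abs(train_scores - q), kind="stable")
        out[i] = train_cells[order[:k]].mean()
    return float(out[0]) if np.ndim(score) == 0 else out


def linear_correction(preds, target_mean: float, target_std: float) -> np.ndarray:
    """Affine-map predictions so their mean and std equal the targets, then
    clip to [0, 1].  Zero-variance input collapses to the target mean."""
    preds = np.asarray(preds, dtype=float).ravel()
    s = preds.std()
    if s == 0:
        logger.warning("zero-variance predictions: returning constant target mean")
        return np.clip(np.full_like(preds, target_mean), 0.0, 1.0)
    corrected = (preds - preds.mean()) / s * target_std + target_mean
    return np.clip(corrected, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Estimators

HUBER_GBDT_PARAMS: dict = {
    "n_estimators": 1500,
    "max_depth": 4,
    "num_leaves": 15,
    "reg_alpha": 0.001,
    "reg_lambda": 0.0,
    "colsample_bytree": 0.6,
    "subsample": 0.7,
    "subsample_freq": 1,
    "learning_rate": 0.01,
    "delta": 1.0,
}

RANKNET_GBDT_PARAMS: dict = {
    "num_boost_round": 1000,
    "max_depth": 3,
    "learning_rate": 0.01,
    "reg_alpha": 0.001,
    "reg_lambda": 0.0,
    "colsample_bytree": 0.6,
    "subsample": 0.8,
    "sigmoid_k": 1.0,
}

SVR_PARAMS: dict = {"C": 200.0, "gamma": 1e-4, "epsilon": 0.0, "kernel": "rbf"}

RANK_SVM_PARAMS: dict = {"C": 1e8, "max_pairs": 4000, "max_iter": 1000}


@dataclass
class EstimatorModel:
    """A fitted cellularity estimator plus its calibration/correction state.

    ``calibration`` is (train_scores, train_cells, k) for the two ranking
    kinds and None for direct regressors; ``correction`` is the affine
    (slope, intercept) fitted on training predictions so that corrected
    training predictions match the training-label mean and std.
    """

    kind: str
    model: object
    params: dict
    seed: int
    calibration: tuple[np.ndarray, np.ndarray, int] | None = None
    correction: tuple[float, float] | None = None
    target_moments: tuple[float, float] | None = None

    def raw_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kind == "huber_gbdt":
            return self.model.booster_.predict(X)
        if self.kind == "ranknet_gbdt":
            return self.model.predict(xgb.DMatrix(X))
        if self.kind == "svr":
            return self.model.predict(X)
        if self.kind == "rank_svm":
            return X @ self.model  # stored weight vector
        raise InvalidParameterError(f"unknown estimator kind {self.kind!r}")

    def predict(self, X) -> np.ndarray:
        """Cellularity in [0, 1]: raw score -> KNN calibration (ranking
        kinds) -> stored linear correction -> clip."""
        scores = self.raw_scores(X)
        if self.calibration is not None:
            ts, tc, k = self.calibration
            scores = np.atleast_1d(knn_calibrate(scores, ts, tc, k))
        if self.correction is not None:
            a, b = self.correction
            scores = a * scores + b
        return np.clip(scores, 0.0, 1.0)


def _fit_huber(X, y, params, seed):
    p = dict(HUBER_GBDT_PARAMS)
    p.update(params or {})
    delta = p.pop("delta")
    model = lgb.LGBMRegressor(
        objective="huber",
        alpha=delta,
        random_state=seed,
        deterministic=True,
        n_jobs=1,
        verbose=-1,
        **p,
    )
    model.fit(X, y)
    return model, p | {"delta": delta}


def _fit_ranknet(X, levels, params, seed):
    p = dict(RANKNET_GBDT_PARAMS)
    p.update(params or {})
    k = float(p["sigmoid_k"])
    lo, hi = _adjacent_pair_arrays(levels)

    def objective(preds, _dtrain):
        z = k * (preds[hi] - preds[lo])
        prob = _sigmoid(z)
        g_pair = -k * (1.0 - prob)       # dL/ds_hi for target orientation 1
        h_pair = k * k * prob * (1.0 - prob)
        grad = np.zeros_like(preds)
        hess = np.zeros_like(preds)
        np.add.at(grad, hi, g_pair)
        np.add.at(grad, lo, -g_pair)
        np.add.at(hess, hi, h_pair)
        np.add.at(hess, lo, h_pair)
        return grad, np.maximum(hess, 1e-9)

    dtrain = xgb.DMatrix(np.asarray(X, dtype=float), label=levels)
    booster = xgb.train(
        {
            "max_depth": int(p["max_depth"]),
            "eta": p["learning_rate"],
            "alpha": p["reg_alpha"],
            "lambda": p["reg_lambda"],
            "colsample_bytree": p["colsample_bytree"],
            "subsample": p["subsample"],
            "base_score": 0.0,
            "seed": seed,
            "nthread": 1,
        },
        dtrain,
        num_boost_round=int(p["num_boost_round"]),
        obj=objective,
    )
    return booster, p


def _fit_svr(X, y, params, seed):
    p = dict(SVR_PARAMS)
    p.update(params or {})
    model = _SkSVR(**p)
    model.fit(X, y)
    return model, p


def _fit_rank_svm(X, levels, params, seed):
    p = dict(RANK_SVM_PARAMS)
    p.update(params or {})
    lo, hi = _adjacent_pair_arrays(levels)
    if lo.size > p["max_pairs"]:
        rng = np.random.default_rng(seed)
        keep = rng.choice(lo.size, size=int(p["max_pairs"]), replace=False)
        keep.sort()
        lo, hi = lo[keep], hi[keep]
    X = np.asarray(X, dtype=float)
    diffs = X[hi] - X[lo]
    data = np.vstack([diffs, -diffs])
    target = np.concatenate([np.ones(len(diffs)), -np.ones(len(diffs))])
    # Squared slack variables (squared hinge) keep the primal strictly
    # convex, so the effectively hard-margin C = 1e8 problem solves in a
    # handful of Newton steps; with linear slacks the dual coordinate
    # solver does not converge at this C.
    svc = LinearSVC(
        C=p["C"],
        loss="squared_hinge",
        dual=False,
        fit_intercept=False,
        max_iter=int(p["max_iter"]),
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(data, target)
    return svc.coef_[0].copy(), p


def train_estimator(
    kind: str,
    X,
    cellularities,
    params: dict | None = None,
    seed: int = 0,
    level_map: LevelMap = DEFAULT_LEVEL_MAP,
    knn_k: int = 30,
    apply_correction: bool = True,
) -> EstimatorModel:
    """Fit one of the four estimator kinds on the cancerous training subset.

    Training cellularities must all be positive (cellularity 0 is produced
    by the tissue gate, never by a regressor); ranking kinds additionally
    need at least two occupied levels.
    """
    if kind not in ESTIMATOR_KINDS:
        raise InvalidParameterError(
            f"kind must be one of {ESTIMATOR_KINDS}, got {kind!r}"
        )
    X = np.asarray(X, dtype=float)
    y = np.asarray(cellularities, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise InvalidInputError("X and cellularities must have equal length")
    if np.any(y <= 0):
        raise InvalidTrainingSetError(
            "regression training requires the cancerous subset (cellularity > 0)"
        )
    levels = cellularity_to_level(y, level_map)

    calibration = None
    if kind == "huber_gbdt":
        model, p = _fit_huber(X, y, params, seed)
    elif kind == "ranknet_gbdt":
        model, p = _fit_ranknet(X, levels, params, seed)
    elif kind == "svr":
        model, p = _fit_svr(X, y, params, seed)
    else:
        model, p = _fit_rank_svm(X, levels, params, seed)

    est = EstimatorModel(kind=kind, model=model, params=p, seed=seed)
    if kind in ("ranknet_gbdt", "rank_svm"):
        train_scores = est.raw_scores(X)
        k_eff = min(knn_k, train_scores.size)
        calibration = (train_scores, y.copy(), k_eff)
        est.calibration = calibration

    if apply_correction:
        train_pred = est.raw_scores(X)
        if calibration is not None:
            ts, tc, k_eff = calibration
            train_pred = np.atleast_1d(knn_calibrate(train_pred, ts, tc, k_eff))
        mu_t, sd_t = float(y.mean()), float(y.std())
        mu_p, sd_p = float(train_pred.mean()), float(train_pred.std())
        if sd_p == 0:
            logger.warning("zero-variance training predictions; constant correction")
            est.correction = (0.0, mu_t)
        else:
            a = sd_t / sd_p
            est.correction = (a, mu_t - a * mu_p)
        est.target_moments = (mu_t, sd_t)
    return est
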