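"""Feature refinement: mRMR selection (MIQ criterion) and PCA reduction.

Minimum-redundancy-maximum-relevance selection greedily builds a feature
subset that is marginally informative about the target while mutually
uninformative.  Relevance and redundancy are mutual information values on
discretized columns: continuous features use the standard 3-bin scheme with
cut points at mean +/- one standard deviation; columns with few distinct
values (the cellularity grid, class labels, already-binned features) are
used as-is.  The MIQ score of a candidate f given the selected set S is

    score(f) = I(f; y) / mean_{s in S} I(f; s)

with the first pick being plain maximum relevance.  Ties break toward the
lower column index, so selection is fully deterministic.

PCA is a thin wrapper around scikit-learn with a fixed sign convention
(the largest-magnitude loading of each component is positive) so that fits
are reproducible across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

#: Columns with at most this many distinct values are treated as already
#: discrete (covers the 37-bin cellularity grid and binary labels).
_DISCRETE_MAX_LEVELS = 40


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of mRMR selection.

    ``ranked_indices`` holds the selected feature indices in pick order
    (the first maximizes relevance); ``relevance`` is the per-feature
    mutual information with the target for *all* input features.
    """

    ranked_indices: np.ndarray
    relevance: np.ndarray
    n_selected: int


@dataclass(frozen=True)
class PcaTransform:
    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance: np.ndarray


def _discretize(col: np.ndarray) -> np.ndarray:
    """Map a column to small integer codes for entropy computations."""
    col = np.asarray(col)
    values = np.unique(col)
    if values.size <= _DISCRETE_MAX_LEVELS:
        return np.searchsorted(values, col)
    m, s = col.mean(), col.std()
    if s == 0:
        return np.zeros(col.shape, dtype=np.intp)
    return np.digitize(col, [m - s, m + s])


def _mi_codes(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two integer-coded columns."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def mutual_information(f, y, n_bins: int = 3) -> float:
    """MI between a feature column and a target column, in nats.

    Each argument is discretized independently: columns with few distinct
    values keep their native bins (so a cellularity target uses the dataset
    grid), continuous columns get ``n_bins`` = 3 bins at mean +/- sd.
    Symmetric in its arguments; constant columns give 0.
    """
    f = np.asarray(f, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if f.shape != y.shape or f.size < 2:
        raise InvalidInputError("columns must have equal length >= 2")
    if n_bins != 3:
        raise InvalidParameterError("only the 3-bin mean±sd scheme is supported")
    return _mi_codes(_discretize(f), _discretize(y))


def mrmr_miq(X, y, n_feat: int) -> SelectionResult:
    """Greedy mRMR selection with the mutual-information-quotient criterion.

    Deterministic: the first feature maximizes I(f; y); each later pick
    maximizes I(f; y) / mean_{s in S} I(f; s), ties broken by index.
    Features with zero relevance can still be picked when ``n_feat``
    demands it (logged).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError("X must be a 2-D table")
    if np.isnan(X).any():
        raise InvalidInputError("X contains NaN")
    n_samples, n_features = X.shape
    if not 1 <= n_feat <= n_features:
        raise InvalidParameterError(
            f"n_feat must be in [1, {n_features}], got {n_feat}"
        )

    codes = [_discretize(X[:, j]) for j in range(n_features)]
    y_code = _discretize(np.asarray(y, dtype=float).ravel())
    relevance = np.array([_mi_codes(c, y_code) for c in codes])

    selected: list[int] = []
    remaining = np.ones(n_features, dtype=bool)
    redundancy_sum = np.zeros(n_features)
    for _ in range(n_feat):
        if not selected:
            score = relevance.copy()
        else:
            mean_red = redundancy_sum / len(selected)
            score = relevance / np.maximum(mean_red, 1e-12)
        score[~remaining] = -np.inf
        pick = int(np.argmax(score))  # argmax -> lowest index on ties
        if relevance[pick] == 0.0:
            logger.info("mRMR selected zero-relevance feature %d", pick)
        selected.append(pick)
        remaining[pick] = False
        mi_new = np.array(
            [_mi_codes(codes[j], codes[pick]) if remaining[j] else 0.0
             for j in range(n_features)]
        )
        redundancy_sum += mi_new
    return SelectionResult(np.asarray(selected, dtype=np.intp), relevance, n_feat)


def fit_pca(X, n_components: int) -> PcaTransform:
    """Fit a PCA rotation keeping the ``n_components`` top-variance axes."""
    X = np.asarray(X, dtype=float)
    if not 1 <= n_components <= min(X.shape):
        raise InvalidParameterError(
            f"n_components must be in [1, {min(X.shape)}], got {n_components}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    model.fit(X)
    components = model.components_.copy()
    # Sign convention: largest-magnitude loading of each component positive.
    flip = np.sign(
        components[np.arange(components.shape[0]),
                   np.argmax(np.abs(components), axis=1)]
    )
    flip[flip == 0] = 1.0
    components *= flip[:, None]
    return PcaTransform(
        mean=model.mean_.copy(),
        components=components,
        explained_variance=model.explained_variance_.copy(),
    )


def apply_pca(transform: PcaTransform, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - transform.mean) @ transform.components.T


#: Named refinement presets per estimator profile: mRMR size per backbone
#: (None = no mRMR) and PCA component count (None = no PCA).
PRESETS: dict[str, dict] = {
    "huber": {
        "n_feat": {"vgg16": 400, "resnet50": 800, "inceptionv3": 1000},
        "pca_components": None,
    },
    "ranknet": {
        "n_feat": {"vgg16": 400, "resnet50": 800, "inceptionv3": 1000},
        "pca_components": None,
    },
    "svr": {
        "n_feat": {"vgg16": 4000, "resnet50": 8000, "inceptionv3": 4000},
        "pca_components": 150,
    },
    "ranksvm": {
        "n_feat": {"vgg16": 50, "resnet50": 50, "inceptionv3": 50},
        "pca_components": 20,
    },
    # The tissue gate skips mRMR and keeps 40 principal components.
    "classifier": {"n_feat": None, "pca_components": 40},
}


def preset_sizes(preset: str, backbone: str, n_features: int,
                 n_samples: int | None = None) -> tuple[int | None, int | None]:
    """Resolve a preset to concrete (n_feat, pca_components) for a table.

    Sizes are capped at what the table can support, so the full-scale
    presets remain usable on small synthetic tables.
    """
    if preset not in PRESETS:
        raise InvalidParameterError(
            f"unknown preset {preset!r}; known: {sorted(PRESETS)}"
        )
    cfg = PRESETS[preset]
    n_feat = cfg["n_feat"]
    if isinstance(n_feat, dict):
        n_feat = n_feat.get(backbone, min(n_features, max(n_feat.values())))
    if n_feat is not None:
        n_feat = min(n_feat, n_features)
    pca = cfg["pca_components"]
    if pca is not None:
        cap = n_feat if n_feat is not None else n_features
        if n_samples is not None:
            cap = min(cap, n_samples)
        pca = min(pca, cap)
    return n_feat, pca
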