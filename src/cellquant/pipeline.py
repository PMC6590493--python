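"""End-to-end pipeline: configuration, fitting, prediction, bundles, CV.

The fitted pipeline chains stain normalization -> dihedral feature pooling
-> per-branch refinement -> the cancerous-tissue gate -> one of the four
estimators.  The gate branch keeps all pooled features and reduces them
with PCA (40 components); the regression branch applies the preset mRMR
selection (and PCA where the preset says so) and trains on the cancerous
subset only — cellularity 0 is produced exclusively by the gate.

All randomness flows from one root seed, expanded per stage with
independent spawns, so a config + seed pair pins every model exactly.
Cross-validation groups folds by patient id by default (train/test splits
of the source data are by patient), falling back to sample-level folds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import classify, refine, regress
from .errors import BundleError, ConfigurationError, InvalidParameterError
from .features import (
    BackboneSpec,
    FixtureExtractor,
    PoolingConfig,
    featurize_patch,
    get_backbone_spec,
)
from .metrics import AgreementReport, agreement_report
from .stain import ReferenceStain, load_reference_stain, normalize_stain

logger = logging.getLogger(__name__)

BUNDLE_FORMAT_VERSION = 1

_ESTIMATOR_ALIASES = {
    "huber": "huber_gbdt",
    "ranknet": "ranknet_gbdt",
    "svr": "svr",
    "ranksvm": "rank_svm",
    "huber_gbdt": "huber_gbdt",
    "ranknet_gbdt": "ranknet_gbdt",
    "rank_svm": "rank_svm",
}

_PRESET_FOR_KIND = {
    "huber_gbdt": "huber",
    "ranknet_gbdt": "ranknet",
    "svr": "svr",
    "rank_svm": "ranksvm",
}


@dataclass
class PipelineConfig:
    """Serializable description of one pipeline variant."""

    backbone: str = "fixture"
    pool_p: float = 3.0
    n_variations: int = 8
    estimator: str = "huber"
    preset: str | None = None          # defaults to the estimator's preset
    estimator_params: dict = field(default_factory=dict)
    n_feat_override: int | None = None  # overrides the preset mRMR size
    gate_params: dict = field(default_factory=dict)
    gate_pca_components: int = 40
    knn_k: int = 30
    n_folds: int = 9
    grouped_folds: bool = True
    normalize_stain: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.estimator not in _ESTIMATOR_ALIASES:
            raise ConfigurationError(f"unknown estimator {self.estimator!r}")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        get_backbone_spec(self.backbone)  # validates the name

    @property
    def estimator_kind(self) -> str:
        return _ESTIMATOR_ALIASES[self.estimator]

    @property
    def preset_name(self) -> str:
        return self.preset or _PRESET_FOR_KIND[self.estimator_kind]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Expand one root seed into per-stage seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def make_extractor(config: PipelineConfig, seed: int):
    if config.backbone == "fixture":
        return FixtureExtractor(seed=seed)
    raise ConfigurationError(
        f"no built-in extractor for backbone {config.backbone!r}; "
        "pass a callable implementing its tap contract"
    )


def featurize_images(
    images,
    config: PipelineConfig,
    extractor=None,
    reference: ReferenceStain | None = None,
) -> np.ndarray:
    """Stain-normalize and featurize a sequence of RGB patches."""
    spec = get_backbone_spec(config.backbone)
    seeds = _spawn_seeds(config.seed, 4)
    if extractor is None:
        extractor = make_extractor(config, seeds[0])
    if reference is None:
        reference = load_reference_stain()
    pooling = PoolingConfig(p=config.pool_p, n_variations=config.n_variations)
    rows = []
    for image in images:
        if config.normalize_stain:
            image = normalize_stain(image, reference)
        rows.append(featurize_patch(image, extractor, spec, pooling))
    return np.vstack(rows)


@dataclass
class FittedPipeline:
    """Refinement transforms + gate + estimator + manifest, as one bundle."""

    config: PipelineConfig
    reference: ReferenceStain
    backbone_spec: BackboneSpec
    gate_pca: refine.PcaTransform
    gate: classify.GateModel
    selection: refine.SelectionResult | None
    estimator_pca: refine.PcaTransform | None
    estimator: regress.EstimatorModel
    manifest: dict = field(default_factory=dict)

    def _regression_features(self, X: np.ndarray) -> np.ndarray:
        if self.selection is not None:
            X = X[:, self.selection.ranked_indices]
        if self.estimator_pca is not None:
            X = refine.apply_pca(self.estimator_pca, X)
        return X

    def gate_proba(self, X) -> np.ndarray:
        return self.gate.predict_proba(refine.apply_pca(self.gate_pca, X))

    def predict_features(self, X) -> np.ndarray:
        """Gated cellularity prediction from pooled feature rows."""
        X = np.asarray(X, dtype=float)
        out = np.zeros(X.shape[0])
        positive = self.gate_proba(X) >= self.gate.threshold
        if positive.any():
            Xr = self._regression_features(X[positive])
            out[positive] = self.estimator.predict(Xr)
        return out

    def predict_images(self, images, extractor=None) -> np.ndarray:
        X = featurize_images(
            images, self.config, extractor=extractor, reference=self.reference
        )
        return self.predict_features(X)


def fit_pipeline(
    X,
    cellularities,
    config: PipelineConfig,
) -> FittedPipeline:
    """Fit gate + estimator on pooled feature rows and their labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(cellularities, dtype=float).ravel()
    seeds = _spawn_seeds(config.seed, 4)
    n_samples, n_features = X.shape

    # Gate branch: no mRMR, PCA to (at most) 40 components.
    _, gate_pca_k = refine.preset_sizes(
        "classifier", config.backbone, n_features, n_samples
    )
    gate_pca_k = min(config.gate_pca_components, gate_pca_k or n_features)
    gate_pca = refine.fit_pca(X, gate_pca_k)
    gate = classify.train_gate(
        refine.apply_pca(gate_pca, X), (y > 0).astype(int),
        params=config.gate_params or None, seed=seeds[1],
    )

    # Regression branch: cancerous subset, preset refinement.
    cancer = y > 0
    Xc, yc = X[cancer], y[cancer]
    n_feat, pca_k = refine.preset_sizes(
        config.preset_name, config.backbone, n_features, Xc.shape[0]
    )
    if config.n_feat_override is not None:
        n_feat = min(int(config.n_feat_override), n_features)
        if pca_k is not None:
            pca_k = min(pca_k, n_feat, Xc.shape[0])
    selection = None
    if n_feat is not None and n_feat < n_features:
        selection = refine.mrmr_miq(Xc, yc, n_feat)
        Xc = Xc[:, selection.ranked_indices]
    est_pca = None
    if pca_k is not None:
        est_pca = refine.fit_pca(Xc, pca_k)
        Xc = refine.apply_pca(est_pca, Xc)
    estimator = regress.train_estimator(
        config.estimator_kind, Xc, yc,
        params=config.estimator_params or None,
        seed=seeds[2], knn_k=config.knn_k,
    )

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "format_version": BUNDLE_FORMAT_VERSION,
        "n_train": int(n_samples),
    }
    return FittedPipeline(
        config=config,
        reference=load_reference_stain(),
        backbone_spec=get_backbone_spec(config.backbone),
        gate_pca=gate_pca,
        gate=gate,
        selection=selection,
        estimator_pca=est_pca,
        estimator=estimator,
        manifest=manifest,
    )


def desk_scale_config(estimator: str = "huber", seed: int = 0) -> PipelineConfig:
    """Pipeline configuration for the synthetic desk-scale experiment.

    Identical to the full-scale defaults except that tree leaves may hold
    as few as 5 samples (fold training sets are a few hundred patches with
    only a handful of benign ones, two orders of magnitude below the
    data scale the printed GBDT settings are calibrated for) and the
    RankNet learning rate follows the same small-sample adjustment as the
    recovery experiment.
    """
    from .synth import DESK_SCALE_ESTIMATOR_PARAMS

    kind = _ESTIMATOR_ALIASES[estimator]
    est_params = dict(DESK_SCALE_ESTIMATOR_PARAMS.get(kind, {}))
    if kind in ("huber_gbdt",):
        est_params.setdefault("min_child_samples", 5)
    return PipelineConfig(
        estimator=estimator,
        seed=seed,
        gate_params={"min_child_samples": 5},
        estimator_params=est_params,
    )


# ---------------------------------------------------------------------------
# Bundles


def save_bundle(pipeline: FittedPipeline, path) -> None:
    """Serialize a fitted pipeline (single-file joblib archive)."""
    payload = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "manifest": pipeline.manifest,
        "pipeline": pipeline,
    }
    joblib.dump(payload, path)


def load_bundle(path) -> FittedPipeline:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt/truncated archive
        raise BundleError(f"cannot read bundle {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise BundleError(f"{path} is not a cellquant bundle")
    if payload["format_version"] != BUNDLE_FORMAT_VERSION:
        raise BundleError(
            f"bundle format {payload['format_version']} unsupported "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    return payload["pipeline"]


# ---------------------------------------------------------------------------
# Cross-validation


def _fold_assignment(groups: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic fold index per sample, grouped by `groups` values."""
    unique = np.unique(groups)
    if unique.size < n_folds:
        raise ConfigurationError(
            f"{n_folds} folds need >= {n_folds} groups, have {unique.size}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(unique.size)
    fold_of_group = {unique[g]: i % n_folds for i, g in enumerate(order)}
    return np.array([fold_of_group[g] for g in groups])


@dataclass
class CvResult:
    fold_reports: list[AgreementReport]
    pooled_report: AgreementReport
    pooled_gate_auc: float
    predictions: pd.DataFrame
    summary: dict

    def to_dict(self) -> dict:
        return {
            "folds": [r.to_dict() for r in self.fold_reports],
            "pooled": self.pooled_report.to_dict(),
            "pooled_gate_auc": self.pooled_gate_auc,
            "summary": self.summary,
        }


def run_cv(
    config: PipelineConfig,
    X,
    cellularities,
    groups=None,
    ci_replicates: int = 200,
) -> CvResult:
    """Grouped k-fold cross-validation of the full (post-featurization)
    pipeline; returns per-fold and pooled agreement plus pooled gate AUC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(cellularities, dtype=float).ravel()
    seeds = _spawn_seeds(config.seed, 8)
    if groups is None or not config.grouped_folds:
        groups = np.arange(y.size)
    groups = np.asarray(groups)
    folds = _fold_assignment(groups, config.n_folds, seeds[5])

    oof_pred = np.full(y.size, np.nan)
    oof_gate = np.full(y.size, np.nan)
    reports = []
    for f in range(config.n_folds):
        test = folds == f
        pipe = fit_pipeline(X[~test], y[~test], config)
        oof_pred[test] = pipe.predict_features(X[test])
        oof_gate[test] = pipe.gate_proba(X[test])
        reports.append(
            agreement_report(
                oof_pred[test], y[test],
                replicates=ci_replicates, seed=seeds[6],
            )
        )
    pooled = agreement_report(
        oof_pred, y, replicates=ci_replicates, seed=seeds[7]
    )
    gate_auc = classify.roc_auc(oof_gate, (y > 0).astype(int))
    summary = {
        name: {
            "mean": float(np.mean([getattr(r, name) for r in reports])),
            "sd": float(np.std([getattr(r, name) for r in reports])),
        }
        for name in ("icc", "tau_b", "p_k")
    }
    predictions = pd.DataFrame(
        {"fold": folds, "cellularity": y, "prediction": oof_pred,
         "gate_proba": oof_gate}
    )
    return CvResult(reports, pooled, gate_auc, predictions, summary)


def feature_curve(
    config: PipelineConfig,
    X,
    cellularities,
    n_feat_grid,
    groups=None,
    ci_replicates: int = 0,
) -> pd.DataFrame:
    """CV P_K as a function of the mRMR selection size."""
    X = np.asarray(X, dtype=float)
    rows = []
    for n_feat in n_feat_grid:
        if n_feat > X.shape[1]:
            raise InvalidParameterError(
                f"n_feat={n_feat} exceeds {X.shape[1]} available features"
            )
        cfg = PipelineConfig(**{**asdict(config), "n_feat_override": int(n_feat)})
        result = run_cv(cfg, X, cellularities, groups=groups,
                        ci_replicates=ci_replicates)
        rows.append({"n_feat": int(n_feat), "p_k": result.pooled_report.p_k,
                     "tau_b": result.pooled_report.tau_b})
    return pd.DataFrame(rows)
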