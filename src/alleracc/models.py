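"""Eight classification methods behind one seeded train/predict contract.

Seven classical methods (Gaussian naive Bayes, radius-neighbours, bagging,
AdaBoost, linear and quadratic discriminant analysis, extra-trees) are
provided by scikit-learn; the eighth is the four-layer LSTM network in
:mod:`alleracc.lstm`.  All hyperparameters are pinned explicit defaults so
every result is reproducible, and every fitted model remembers the feature
names it was trained on, refusing mismatched inputs at prediction time.

The allergen class is positive (label 1); hard calls use score >= 0.5, so
an exact tie goes to allergen — the conservative choice for a safety
screen.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier, ExtraTreesClassifier
from sklearn.metrics import pairwise_distances
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import RadiusNeighborsClassifier

from . import __version__
from .acc import FeatureMatrix
from .io import ALLERGEN
from .lstm import LSTMClassifier, LSTMConfig

CLASSIFIER_KINDS = (
    "gaussian_nb", "radius_neighbors", "bagging", "adaboost",
    "lda", "qda", "extra_trees", "lstm",
)

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "gaussian_nb": {},
    # radius="median_pairwise": the median pairwise training distance, so the
    # ball is wide enough that empty neighbourhoods are rare; empty ones get
    # the majority training label.
    "radius_neighbors": {"radius": "median_pairwise"},
    "bagging": {"n_estimators": 200},
    "adaboost": {"n_estimators": 100},
    "lda": {},
    # ridge on the class covariances: ACC features are collinear enough that
    # the unregularized class covariance can be rank-deficient
    "qda": {"reg_param": 1e-3},
    "extra_trees": {"n_estimators": 200},
    "lstm": {},
}

_ARTIFACT_FORMAT_VERSION = 1
_METADATA_FILE = "metadata.json"
_STATE_FILE = "model.joblib"


class ModelError(RuntimeError):
    """Training, prediction or persistence contract violation."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative description of one classification method."""

    kind: str
    seed: int
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; choose from {CLASSIFIER_KINDS}")

    def resolved_hyperparams(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMS[self.kind])
        params.update(self.hyperparams)
        return params


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reuse it safely."""

    spec: ClassifierSpec
    estimator: object
    feature_names: tuple[str, ...]
    training_meta: dict

    def _check_features(self, features: FeatureMatrix) -> None:
        if tuple(features.feature_names) != tuple(self.feature_names):
            raise ModelError(
                f"feature-name mismatch: model trained on {len(self.feature_names)} "
                f"named features, input carries {len(features.feature_names)}"
            )


def labels_to_binary(labels: list[str]) -> np.ndarray:
    """Class labels -> 0/1 with allergen = 1 (the positive class)."""
    return np.array([1 if lab == ALLERGEN else 0 for lab in labels], dtype=int)


def _median_pairwise_radius(X: np.ndarray, seed: int, max_rows: int = 500) -> float:
    rows = X
    if X.shape[0] > max_rows:
        idx = np.random.default_rng(seed).choice(X.shape[0], size=max_rows, replace=False)
        rows = X[idx]
    dist = pairwise_distances(rows)
    upper = dist[np.triu_indices_from(dist, k=1)]
    return float(np.median(upper))


def _build_classical(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray):
    params = spec.resolved_hyperparams()
    seed = spec.seed
    if spec.kind == "gaussian_nb":
        return GaussianNB(**params)
    if spec.kind == "radius_neighbors":
        radius = params.pop("radius")
        if radius == "median_pairwise":
            radius = _median_pairwise_radius(X, seed)
        majority = int(np.bincount(y).argmax())
        return RadiusNeighborsClassifier(radius=radius, outlier_label=majority, **params)
    if spec.kind == "bagging":
        return BaggingClassifier(random_state=seed, **params)
    if spec.kind == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis(**params)
    if spec.kind == "qda":
        return QuadraticDiscriminantAnalysis(**params)
    if spec.kind == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, **params)
    raise ValueError(spec.kind)  # pragma: no cover


def train(spec: ClassifierSpec, features: FeatureMatrix) -> TrainedModel:
    """Fit one method on a labeled feature matrix; deterministic per seed."""
    if features.labels is None:
        raise ModelError("training requires a labeled feature matrix")
    X = features.values
    if not np.all(np.isfinite(X)):
        raise ModelError("training features contain non-finite values")
    y = labels_to_binary(features.labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ModelError(
            f"need at least 2 samples per class, got {counts[1]} allergen / "
            f"{counts[0]} non-allergen"
        )
    if spec.kind == "lstm":
        config = LSTMConfig(seed=spec.seed, **spec.resolved_hyperparams())
        return train_lstm(features, config, spec=spec)
    estimator = _build_classical(spec, X, y)
    with warnings.catch_warnings():
        # collinear ACC features make the discriminant solvers chatty
        warnings.filterwarnings("ignore", message="Variables are collinear")
        estimator.fit(X, y)
    model = TrainedModel(
        spec=spec,
        estimator=estimator,
        feature_names=tuple(features.feature_names),
        training_meta={
            "n_samples": int(len(y)),
            "class_counts": {"non_allergen": int(counts[0]), "allergen": int(counts[1])},
            "seed": spec.seed,
            "hyperparams": _jsonable(spec.resolved_hyperparams()),
        },
    )
    model.training_meta["training_accuracy"] = float(
        np.mean(predict_labels(model, features) == y))
    return model


def train_lstm(features: FeatureMatrix, config: LSTMConfig,
               spec: ClassifierSpec | None = None) -> TrainedModel:
    """Fit the four-layer LSTM network on ACC features."""
    if features.labels is None:
        raise ModelError("training requires a labeled feature matrix")
    y = labels_to_binary(features.labels)
    if len(set(y.tolist())) < 2:
        raise ModelError("labels are all one class")
    estimator = LSTMClassifier(config).fit(features.values, y)
    if spec is None:
        spec = ClassifierSpec(kind="lstm", seed=config.seed)
    model = TrainedModel(
        spec=spec,
        estimator=estimator,
        feature_names=tuple(features.feature_names),
        training_meta={
            "n_samples": int(len(y)),
            "class_counts": {
                "non_allergen": int(np.sum(y == 0)),
                "allergen": int(np.sum(y == 1)),
            },
            "seed": config.seed,
            "hyperparams": _jsonable(vars(config)),
            "final_loss": estimator.loss_history_[-1],
        },
    )
    model.training_meta["training_accuracy"] = float(
        np.mean(predict_labels(model, features) == y))
    return model


def predict_proba(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Per-sample allergen-class score in [0, 1]."""
    model._check_features(features)
    if features.n_samples == 0:
        raise ModelError("empty feature matrix")
    proba = model.estimator.predict_proba(features.values)
    return np.asarray(proba)[:, 1]


def predict_labels(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Hard 0/1 calls: allergen iff score >= 0.5 (ties to allergen)."""
    return (predict_proba(model, features) >= 0.5).astype(int)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model as a directory: metadata.json + serialized state."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    metadata = {
        "format_version": _ARTIFACT_FORMAT_VERSION,
        "package_version": __version__,
        "spec": {"kind": model.spec.kind, "seed": model.spec.seed,
                 "hyperparams": _jsonable(model.spec.hyperparams)},
        "feature_names": list(model.feature_names),
        "training_meta": _jsonable(model.training_meta),
    }
    (path / _METADATA_FILE).write_text(json.dumps(metadata, indent=2))
    joblib.dump(model.estimator, path / _STATE_FILE)


def load_model(path: str | Path, allow_version_mismatch: bool = False) -> TrainedModel:
    """Load a persisted model; refuses artifacts from other format versions."""
    path = Path(path)
    meta_path = path / _METADATA_FILE
    state_path = path / _STATE_FILE
    if not meta_path.exists() or not state_path.exists():
        raise ModelError(f"{path} is not a model artifact directory")
    try:
        metadata = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"corrupt model metadata in {meta_path}: {exc}") from exc
    version = metadata.get("format_version")
    if version != _ARTIFACT_FORMAT_VERSION and not allow_version_mismatch:
        raise ModelError(
            f"artifact format version {version} != supported "
            f"{_ARTIFACT_FORMAT_VERSION}; pass allow_version_mismatch=True to force"
        )
    try:
        estimator = joblib.load(state_path)
    except Exception as exc:
        raise ModelError(f"failed to load model state from {state_path}: {exc}") from exc
    spec_meta = metadata["spec"]
    return TrainedModel(
        spec=ClassifierSpec(kind=spec_meta["kind"], seed=spec_meta["seed"],
                            hyperparams=spec_meta.get("hyperparams", {})),
        estimator=estimator,
        feature_names=tuple(metadata["feature_names"]),
        training_meta=metadata["training_meta"],
    )
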