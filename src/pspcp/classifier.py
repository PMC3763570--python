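"""RBF-kernel support vector classification over descriptor vectors.

The decision model is a multiclass SVM with the radial basis function kernel

    K(x, y) = exp(-gamma * ||x - y||^2),

trained one-vs-one with majority voting (the libsvm default).  Descriptor
vectors already share a sum-to-1 normalization, so no additional feature
scaling is applied before training.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .features import FeatureConfig


class ModelError(ValueError):
    """Raised for invalid training inputs or model/config mismatches."""


def rbf_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||x - y||^2) for two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ModelError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if gamma <= 0:
        raise ModelError(f"gamma must be positive, got {gamma}")
    diff = x - y
    return float(np.exp(-gamma * diff.dot(diff)))


@dataclass(frozen=True)
class ModelConfig:
    """SVM hyperparameters plus the feature configuration they apply to."""

    gamma: float = 0.125
    C: float = 8.0
    feature_config: FeatureConfig | None = None
    class_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ModelError(f"gamma must be positive, got {self.gamma}")
        if self.C <= 0:
            raise ModelError(f"C must be positive, got {self.C}")
        object.__setattr__(self, "class_labels", tuple(self.class_labels))


def _fingerprint(X: np.ndarray, y) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update("\x00".join(str(v) for v in y).encode())
    return h.hexdigest()


class LocationSVC(ClassifierMixin, BaseEstimator):
    """Multiclass RBF-SVM for protein location prediction.

    A thin, validated wrapper around libsvm (via scikit-learn's ``SVC``)
    with hard-label output, one-vs-one multiclass voting, and a training
    fingerprint for reproducibility checks.

    Parameters
    ----------
    gamma : float, default 0.125
        RBF kernel width.
    C : float, default 8.0
        Soft-margin cost.

    Attributes
    ----------
    classes_ : ndarray of class labels seen in fit
    svc_ : the fitted solver
    n_features_in_ : int
    training_fingerprint_ : str
        SHA-256 of the training matrix and labels; identical retrains on
        identical inputs produce identical fingerprints.
    """

    def __init__(self, gamma: float = 0.125, C: float = 8.0):
        self.gamma = gamma
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ModelError(
                f"X has shape {X.shape} but y has {y.shape[0]} labels"
            )
        if not np.all(np.isfinite(X)):
            raise ModelError("training features contain NaN or infinite values")
        classes = np.unique(y)
        if classes.size < 2:
            raise ModelError(
                f"training needs >= 2 classes, got {classes.tolist()}"
            )
        if self.gamma <= 0 or self.C <= 0:
            raise ModelError("gamma and C must be positive")
        # libsvm trains one-vs-one; random_state pinned for any internal
        # stochastic step so retrains are bit-reproducible
        self.svc_ = SVC(
            kernel="rbf", gamma=self.gamma, C=self.C, random_state=0,
            cache_size=64,
        )
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        self.training_fingerprint_ = _fingerprint(X, y)
        return self

    def predict(self, X):
        if not hasattr(self, "svc_"):
            raise ModelError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            return np.array([], dtype=self.classes_.dtype)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ModelError(
                f"feature dimension {X.shape[1] if X.ndim == 2 else X.shape} "
                f"does not match training dimension {self.n_features_in_}"
            )
        return self.svc_.predict(X)


@dataclass
class TrainedModel:
    """A fitted classifier plus the configuration that produced it."""

    estimator: LocationSVC
    config: ModelConfig
    feature_names: list[str] = field(default_factory=list)

    @property
    def training_fingerprint(self) -> str:
        return self.estimator.training_fingerprint_


def train(X, y, config: ModelConfig, feature_names=None) -> TrainedModel:
    """Fit an RBF-SVM on a descriptor matrix (functional wrapper)."""
    est = LocationSVC(gamma=config.gamma, C=config.C).fit(X, y)
    cfg = ModelConfig(
        gamma=config.gamma,
        C=config.C,
        feature_config=config.feature_config,
        class_labels=tuple(str(c) for c in est.classes_),
    )
    return TrainedModel(est, cfg, list(feature_names or []))


def predict(model: TrainedModel, X) -> list:
    """Hard labels for each row of X (functional wrapper)."""
    return list(model.estimator.predict(X))


def save_model(model: TrainedModel, path) -> None:
    """Persist a model as a joblib archive plus a JSON sidecar.

    The sidecar records hyperparameters, class labels, feature names and the
    training fingerprint; :func:`load_model` verifies them against the
    unpickled estimator.
    """
    path = Path(path)
    joblib.dump(model.estimator, path)
    fc = model.config.feature_config
    sidecar = {
        "gamma": model.config.gamma,
        "C": model.config.C,
        "class_labels": list(model.config.class_labels),
        "feature_names": model.feature_names,
        "n_features": model.estimator.n_features_in_,
        "training_fingerprint": model.training_fingerprint,
        "feature_config": None
        if fc is None
        else {
            "w": fc.w,
            "lambda": fc.lam,
            "property_accessions": list(fc.property_accessions),
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2), encoding="utf-8"
    )


def load_model(path) -> TrainedModel:
    """Load a persisted model, verifying sidecar consistency."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise ModelError(f"missing model sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
    est = joblib.load(path)
    if est.n_features_in_ != sidecar["n_features"]:
        raise ModelError(
            f"sidecar says {sidecar['n_features']} features but model has "
            f"{est.n_features_in_}"
        )
    if [str(c) for c in est.classes_] != list(sidecar["class_labels"]):
        raise ModelError("sidecar class labels do not match the model")
    if est.training_fingerprint_ != sidecar["training_fingerprint"]:
        raise ModelError("training fingerprint mismatch: archive corrupted?")
    fc = sidecar.get("feature_config")
    feature_config = (
        None
        if fc is None
        else FeatureConfig(
            w=fc["w"],
            lam=fc["lambda"],
            property_accessions=tuple(fc["property_accessions"]),
        )
    )
    config = ModelConfig(
        gamma=sidecar["gamma"],
        C=sidecar["C"],
        feature_config=feature_config,
        class_labels=tuple(sidecar["class_labels"]),
    )
    return TrainedModel(est, config, list(sidecar["feature_names"]))
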