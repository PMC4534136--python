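"""Pixel classifiers producing skin posteriors and binary masks.

Four classifier kinds are supported with defaults matching the evaluation
protocol: a 15-tree random forest, a kernel-density naive Bayes, a degree-3
polynomial SVM (C=1, tol=1e-3) with Platt-calibrated probabilities, and a
5-layer MLP (3 hidden layers of round((k+2)/2) units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .colorspaces import ComponentRegistry, RgbImage, SkinMask, transform
from .skn import HybridSpace, apply_hybrid, rgb_image_to_skn

__all__ = [
    "ClassifierSpec",
    "TrainedModel",
    "CLASSIFIER_KINDS",
    "train",
    "predict_proba",
    "predict_mask",
    "pixel_features",
]

CLASSIFIER_KINDS = ("random_forest", "naive_bayes", "svm", "mlp")

_TRAIN_CAP = 200_000  # default stratified pixel cap for training
_SVM_CAP = 10_000  # SVC training is quadratic in n
_NB_CAP_PER_CLASS = 5_000  # kernel-density fitting subsample


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    params: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; valid: {CLASSIFIER_KINDS}"
            )
        object.__setattr__(self, "params", dict(self.params))


class _KernelDensityNB:
    """Naive Bayes with a per-feature Gaussian KDE class-conditional model.

    Silverman's rule sets the bandwidth.  A small density floor keeps
    log-posteriors finite far from the training support.
    """

    _FLOOR = 1e-300

    def __init__(self, seed: int, cap_per_class: int = _NB_CAP_PER_CLASS):
        self.seed = seed
        self.cap = cap_per_class

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_KernelDensityNB":
        rng = np.random.default_rng(self.seed)
        self.classes_ = np.unique(y)
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        self.kdes_: list[list[gaussian_kde]] = []
        for c in self.classes_:
            Xc = X[y == c]
            if Xc.shape[0] > self.cap:
                Xc = Xc[rng.choice(Xc.shape[0], self.cap, replace=False)]
            feats = []
            for j in range(X.shape[1]):
                col = Xc[:, j]
                if np.ptp(col) == 0.0:  # degenerate feature: widen slightly
                    col = col + rng.normal(0.0, 1e-9, size=col.size)
                feats.append(gaussian_kde(col, bw_method="silverman"))
            self.kdes_.append(feats)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logp = np.zeros((X.shape[0], self.classes_.size))
        for ci in range(self.classes_.size):
            logp[:, ci] = np.log(self.priors_[ci])
            for j, kde in enumerate(self.kdes_[ci]):
                logp[:, ci] += np.log(np.maximum(kde(X[:, j]), self._FLOOR))
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _hidden_width(k: int) -> int:
    """round((k + 2) / 2) with half-up rounding (k=3 -> 3)."""
    return int(np.floor((k + 2) / 2 + 0.5))


def _build_estimator(spec: ClassifierSpec, k: int):
    p = dict(spec.params)
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=p.pop("n_trees", 15),
            random_state=spec.seed,
            n_jobs=1,
            **p,
        )
    if spec.kind == "naive_bayes":
        return _KernelDensityNB(seed=spec.seed, cap_per_class=p.pop("cap_per_class", _NB_CAP_PER_CLASS))
    if spec.kind == "svm":
        svc = SVC(
            kernel="poly",
            degree=p.pop("degree", 3),
            C=p.pop("C", 1.0),
            tol=p.pop("tol", 1e-3),
            random_state=spec.seed,
            **p,
        )
        # Platt-style sigmoid calibration on held-out folds for posteriors
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)
    if spec.kind == "mlp":
        h = p.pop("hidden_width", _hidden_width(k))
        # tiny hidden layers train unreliably with relu on raw features;
        # standardized inputs + tanh keep the 3x(h) topology trainable
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(h, h, h),
                activation="tanh",
                learning_rate_init=0.05,
                random_state=spec.seed,
                early_stopping=True,
                n_iter_no_change=30,
                max_iter=p.pop("max_iter", 1000),
                **p,
            ),
        )
    raise AssertionError(spec.kind)


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    feature_ids: tuple[str, ...]

    def _check_ids(self, feature_ids: Sequence[str] | None) -> None:
        if feature_ids is not None and tuple(feature_ids) != self.feature_ids:
            raise ValueError(
                f"feature ids {tuple(feature_ids)} do not match training ids "
                f"{self.feature_ids}"
            )


def train(
    spec: ClassifierSpec,
    features: np.ndarray,
    labels: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    max_pixels: int = _TRAIN_CAP,
) -> TrainedModel:
    """Fit a classifier on pixel features; stratified-caps very large inputs."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be n x k with one label per row")
    if np.unique(y).size < 2:
        raise ValueError("training labels must contain both classes")
    cap = min(max_pixels, _SVM_CAP) if spec.kind == "svm" else max_pixels
    if X.shape[0] > cap:
        rng = np.random.default_rng(spec.seed)
        parts = []
        for c in (0, 1):
            idx = np.flatnonzero(y == c)
            take = max(1, int(round(cap * idx.size / y.size)))
            parts.append(rng.choice(idx, size=min(take, idx.size), replace=False))
        keep = np.sort(np.concatenate(parts))
        X, y = X[keep], y[keep]
    est = _build_estimator(spec, X.shape[1])
    est.fit(X, y)
    ids = tuple(feature_ids) if feature_ids is not None else tuple(
        f"f{i}" for i in range(X.shape[1])
    )
    return TrainedModel(spec=spec, estimator=est, feature_ids=ids)


def predict_proba(
    model: TrainedModel,
    features: np.ndarray,
    feature_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Skin (class 1) posterior for each feature row, in [0, 1]."""
    model._check_ids(feature_ids)
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or len(model.feature_ids) != X.shape[1]:
        raise ValueError("feature width does not match the trained model")
    proba = model.estimator.predict_proba(X)
    classes = np.asarray(model.estimator.classes_)
    col = int(np.flatnonzero(classes == 1)[0])
    return np.clip(proba[:, col], 0.0, 1.0)


def pixel_features(
    image: RgbImage | np.ndarray,
    space: HybridSpace | str,
    registry: ComponentRegistry | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Per-pixel feature rows for an image in the given space.

    ``space`` may be a :class:`HybridSpace`, the name ``"skn"``, or any
    registry color-space name (e.g. ``"HSV"``).
    """
    if isinstance(space, HybridSpace):
        planes = apply_hybrid(space, image, registry)
        ids = tuple(f"{space.name}:{i}" for i in range(planes.shape[-1]))
        return planes.reshape(-1, planes.shape[-1]), ids
    if space.lower() == "skn":
        planes = rgb_image_to_skn(image)
        return planes.reshape(-1, 3), ("skn:S", "skn:K", "skn:N")
    plane_map = transform(image, space)
    names = tuple(plane_map)
    stack = np.stack([plane_map[n] for n in names], axis=-1)
    return stack.reshape(-1, len(names)), tuple(f"{space}:{n}" for n in names)


def predict_mask(
    model: TrainedModel,
    image: RgbImage,
    space: HybridSpace | str,
    threshold: float = 0.5,
    registry: ComponentRegistry | None = None,
) -> SkinMask:
    """Binary skin mask: 1 where the posterior is >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    X, ids = pixel_features(image, space, registry)
    post = predict_proba(model, X, ids)
    return SkinMask((post >= threshold).astype(np.uint8).reshape(image.height, image.width))
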