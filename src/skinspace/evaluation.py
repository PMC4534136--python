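"""Confusion counting, detection metrics, ROC curves and error overlays.

Metric definitions: TPR = TP / (TP + FN), FPR = FP / (FP + TN),
precision = TP / (TP + FP), F = 2 TP / (2 TP + FP + FN).

Zero-denominator policy: an image with no skin pixels is excluded from
TPR/F averages (an image with no non-skin pixels likewise from FPR);
precision with TP + FP = 0 is defined as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .colorspaces import RgbImage, SkinMask
from .skn import HybridSpace

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "RocCurve",
    "confusion",
    "metrics",
    "average_over_images",
    "evaluate_pairs",
    "roc",
    "roc_from_scores",
    "annotate_errors",
]

N_ROC_THRESHOLDS = 50


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def n_skin(self) -> int:
        return self.TP + self.FN

    @property
    def n_non_skin(self) -> int:
        return self.FP + self.TN


@dataclass(frozen=True)
class MetricSet:
    TPR: float
    FPR: float
    precision: float
    f_score: float

    def as_dict(self) -> dict:
        return {
            "TPR": self.TPR,
            "FPR": self.FPR,
            "precision": self.precision,
            "f_score": self.f_score,
        }


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=np.float64)
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "tpr", np.asarray(self.tpr, dtype=np.float64))
        object.__setattr__(self, "fpr", np.asarray(self.fpr, dtype=np.float64))
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ValueError("auc must be in [0, 1]")


def confusion(pred: SkinMask, truth: SkinMask) -> ConfusionCounts:
    """Pixel-level confusion counts between a predicted and true mask."""
    if pred.labels.shape != truth.labels.shape:
        raise ValueError(
            f"mask shapes differ: {pred.labels.shape} vs {truth.labels.shape}"
        )
    p = pred.labels.astype(bool)
    t = truth.labels.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
        TN=int(np.sum(~p & ~t)),
    )


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Detection metrics from confusion counts (NaN where undefined)."""
    tp, fp, fn, tn = counts.TP, counts.FP, counts.FN, counts.TN
    tpr = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    fpr = fp / (fp + tn) if (fp + tn) > 0 else math.nan
    prec = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else math.nan
    return MetricSet(TPR=tpr, FPR=fpr, precision=prec, f_score=f)


def average_over_images(per_image: Sequence[MetricSet]) -> MetricSet:
    """Unweighted mean of each metric; NaN entries (degenerate images) drop out."""
    if not per_image:
        raise ValueError("cannot average an empty metric list")

    def mean_of(vals: list[float]) -> float:
        vals = [v for v in vals if not math.isnan(v)]
        if not vals:
            raise ValueError("all images were degenerate for this metric")
        return float(np.mean(vals))

    return MetricSet(
        TPR=mean_of([m.TPR for m in per_image]),
        FPR=mean_of([m.FPR for m in per_image]),
        precision=mean_of([m.precision for m in per_image]),
        f_score=mean_of([m.f_score for m in per_image]),
    )


def evaluate_pairs(
    model,
    pairs: Iterable[tuple[RgbImage, SkinMask]],
    space: HybridSpace | str,
    threshold: float = 0.5,
) -> tuple[MetricSet, list[MetricSet]]:
    """Image-averaged metrics of a trained model over test pairs."""
    from .classifiers import predict_mask

    per_image = []
    for image, truth in pairs:
        pred = predict_mask(model, image, space, threshold)
        per_image.append(metrics(confusion(pred, truth)))
    return average_over_images(per_image), per_image


def _auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal area with (0,0) and (1,1) anchors, sorted by FPR then TPR."""
    f = np.concatenate([[0.0], fpr, [1.0]])
    t = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((t, f))
    f, t = f[order], t[order]
    return float(np.trapezoid(t, f))


def roc_from_scores(
    scored_images: Sequence[tuple[np.ndarray, np.ndarray]],
    n_thresholds: int = N_ROC_THRESHOLDS,
) -> RocCurve:
    """ROC over (posterior, truth) pixel arrays, image-averaged per threshold.

    Thresholds are ``n_thresholds`` evenly spaced values on [0, 1]; a pixel
    is predicted skin when its posterior >= threshold.
    """
    if not scored_images:
        raise ValueError("no scored images supplied")
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    tprs, fprs = [], []
    for thr in thresholds:
        t_vals, f_vals = [], []
        for scores, truth in scored_images:
            truth = np.asarray(truth).astype(bool).ravel()
            pred = np.asarray(scores).ravel() >= thr
            n_s = int(truth.sum())
            n_ns = truth.size - n_s
            if n_s > 0:
                t_vals.append(np.sum(pred & truth) / n_s)
            if n_ns > 0:
                f_vals.append(np.sum(pred & ~truth) / n_ns)
        if not t_vals or not f_vals:
            raise ValueError("every image is degenerate (single-class truth)")
        tprs.append(float(np.mean(t_vals)))
        fprs.append(float(np.mean(f_vals)))
    tpr = np.array(tprs)
    fpr = np.array(fprs)
    return RocCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=_auc_trapezoid(fpr, tpr),
    )


def roc(
    model,
    pairs: Sequence[tuple[RgbImage, SkinMask]],
    space: HybridSpace | str,
    n_thresholds: int = N_ROC_THRESHOLDS,
) -> RocCurve:
    """ROC curve of a trained model over test pairs."""
    from .classifiers import pixel_features, predict_proba

    if not pairs:
        raise ValueError("test set must be non-empty")
    scored = []
    for image, truth in pairs:
        X, ids = pixel_features(image, space)
        scored.append((predict_proba(model, X, ids), truth.labels))
    return roc_from_scores(scored, n_thresholds)


def annotate_errors(image: RgbImage, pred: SkinMask, truth: SkinMask) -> RgbImage:
    """Error overlay: TP keeps the original color, FN red, FP blue, TN white."""
    if (pred.labels.shape != truth.labels.shape) or (
        truth.labels.shape != image.pixels.shape[:2]
    ):
        raise ValueError("image, prediction and truth dimensions must match")
    p = pred.labels.astype(bool)
    t = truth.labels.astype(bool)
    out = np.ones_like(image.pixels)  # TN default: white
    out[p & t] = image.pixels[p & t]
    out[~p & t] = (1.0, 0.0, 0.0)  # FN: red
    out[p & ~t] = (0.0, 0.0, 1.0)  # FP: blue
    return RgbImage(out)
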