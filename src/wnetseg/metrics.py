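"""Dice similarity, Dice loss, and auxiliary overlap metrics.

For a ground-truth pixel set X and predicted set Y the Dice similarity
coefficient is ``2|X ∩ Y| / (|X| + |Y|)`` and the training loss is its
complement ``1 - Dice``.  Liver pixels are outnumbered roughly 1:15 by
background in abdominal CT, which is why an overlap-based loss is used here
instead of pixel-wise cross-entropy (the latter is dominated by the easy
background class).  Training uses the *soft* Dice — computed on probabilities
with a smoothing constant so that it is differentiable and defined when both
masks are empty; evaluation hard-thresholds the probabilities first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BothEmptyWarning",
    "MaskPair",
    "dice_coefficient",
    "soft_dice",
    "soft_dice_with_grad",
    "dice_loss",
    "auxiliary_metrics",
]


class BothEmptyWarning(UserWarning):
    """Both masks are empty; Dice is defined as 1.0 by convention."""


@dataclass
class MaskPair:
    """A predicted map (probabilities in [0,1] or binary) and a binary truth."""

    prediction: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        self.prediction = np.asarray(self.prediction, dtype=float)
        self.truth = np.asarray(self.truth)
        if self.prediction.shape != self.truth.shape:
            raise ValueError(
                f"shape mismatch: prediction {self.prediction.shape} vs "
                f"truth {self.truth.shape}"
            )
        if not np.isin(self.truth, (0, 1)).all():
            raise ValueError("truth mask must be strictly binary (0/1)")
        if self.prediction.min() < 0 or self.prediction.max() > 1:
            raise ValueError("prediction values must lie in [0, 1]")
        self.truth = self.truth.astype(float)

    def dice(self, threshold: float = 0.5) -> float:
        return dice_coefficient(self, threshold=threshold)

    def loss(self, smooth: float = 1.0) -> float:
        return dice_loss(self, smooth=smooth)


def _unpack(pair, truth):
    if isinstance(pair, MaskPair):
        if truth is not None:
            raise TypeError("pass either a MaskPair or two arrays, not both")
        return pair.prediction, pair.truth
    mp = MaskPair(pair, truth)
    return mp.prediction, mp.truth


def dice_coefficient(pair, truth=None, *, threshold: float = 0.5) -> float:
    """Hard Dice ``2|X∩Y|/(|X|+|Y|)`` after binarising the prediction.

    If both masks are empty the coefficient is defined as 1.0 (perfect
    agreement on absence) and a :class:`BothEmptyWarning` is issued.
    """
    pred, t = _unpack(pair, truth)
    y = (pred >= threshold).astype(float)
    inter = float((y * t).sum())
    total = float(y.sum() + t.sum())
    if total == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", BothEmptyWarning)
        return 1.0
    return 2.0 * inter / total


def soft_dice(pair, truth=None, *, smooth: float = 1.0) -> float:
    """Differentiable Dice ``(2 Σ p·t + s) / (Σ p + Σ t + s)``.

    On binary predictions this converges to the hard coefficient as the
    smoothing constant ``s`` goes to zero.
    """
    if smooth < 0:
        raise ValueError(f"smooth must be non-negative, got {smooth}")
    pred, t = _unpack(pair, truth)
    num = 2.0 * float((pred * t).sum()) + smooth
    den = float(pred.sum() + t.sum()) + smooth
    if den == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", BothEmptyWarning)
        return 1.0
    return num / den


def soft_dice_with_grad(pred: np.ndarray, truth: np.ndarray,
                        smooth: float = 1.0):
    """Per-sample soft Dice over a batch plus its gradient w.r.t. ``pred``.

    ``pred``/``truth`` have shape ``(n, ...)``; sums run over each sample's
    pixels.  Returns ``(values, grad)`` where ``values`` has shape ``(n,)``.
    Used by the training loop; the quotient-rule gradient is
    ``(2 t (Σp+Σt+s) − (2 Σpt + s)) / (Σp+Σt+s)²`` per pixel.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    axes = tuple(range(1, pred.ndim))
    inter = (pred * truth).sum(axis=axes)
    psum = pred.sum(axis=axes)
    tsum = truth.sum(axis=axes)
    num = 2.0 * inter + smooth
    den = psum + tsum + smooth
    values = num / den
    shape = (-1,) + (1,) * (pred.ndim - 1)
    grad = (2.0 * truth * den.reshape(shape) - num.reshape(shape)) / (
        den ** 2
    ).reshape(shape)
    return values, grad


def dice_loss(pair, truth=None, *, smooth: float = 1.0) -> float:
    """The training objective ``1 - soft Dice``."""
    return 1.0 - soft_dice(pair, truth, smooth=smooth)


def auxiliary_metrics(pair, truth=None, *, threshold: float = 0.5) -> dict:
    """IoU (Jaccard), precision, and recall after thresholding.

    Empty-set conventions mirror :func:`dice_coefficient`: an undefined
    quotient with perfect agreement on absence counts as 1.0.
    """
    pred, t = _unpack(pair, truth)
    y = (pred >= threshold).astype(float)
    inter = float((y * t).sum())
    union = float(np.maximum(y, t).sum())
    ysum, tsum = float(y.sum()), float(t.sum())
    return {
        "iou": inter / union if union else 1.0,
        "precision": inter / ysum if ysum else (1.0 if tsum == 0 else 0.0),
        "recall": inter / tsum if tsum else (1.0 if ysum == 0 else 0.0),
    }
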