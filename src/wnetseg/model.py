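"""Scikit-learn-style estimator wrapping the W-Net graph and numpy trainer.

:class:`WNetSegmenter` is a per-pixel binary classifier: ``fit(X, y)`` takes
grayscale slices ``X`` of shape ``(n, h, w)`` (values in [0, 1] or 0-255)
with binary masks ``y`` of the same shape, minimises the smoothed Dice loss
with Adam, and exposes ``predict_proba``/``predict``/``score``.  It follows
sklearn conventions (constructor stores hyperparameters untouched,
``get_params``/``set_params`` work, fitted state lives in trailing-underscore
attributes), so it composes with ``sklearn.base.clone`` and model selection.

Reference full-scale training recipe, kept as the defaults: Adam with learning rate
1e-5, 10 epochs, 3x3 filters, 2x2 pooling, dropout 0.5 on contracting and
0.4 on expanding paths, 256x256 inputs with the 64->1024 filter schedule.
Desk-scale work uses smaller filters/images and a larger learning rate; see
``docs/methods.md``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .architecture import build_wnet
from .metrics import dice_coefficient, soft_dice_with_grad

__all__ = ["TrainHistory", "WNetSegmenter", "save_weights", "load_weights"]


@dataclass
class TrainHistory:
    """Per-epoch loss and Dice curves (validation entries may stay empty)."""

    loss: list = field(default_factory=list)
    train_dice: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)

    def as_frame(self):
        import pandas as pd

        data = {"epoch": list(range(1, len(self.loss) + 1)),
                "loss": self.loss, "train_dice": self.train_dice}
        if self.val_dice:
            data["val_loss"] = self.val_loss
            data["val_dice"] = self.val_dice
        return pd.DataFrame(data)


class WNetSegmenter(BaseEstimator):
    """Stacked two-U-Net segmenter trained with the smoothed Dice loss.

    Parameters
    ----------
    variant : {"unet", "original_bridge", "modified_bridge", "compound"}
        Which bridge families join the two U-Nets; "compound" activates all
        three (B1->B4, B2->B3, B2->B4).
    base_filters : int
        Filters at level 1, doubled per level (64 -> 1024 and 32 -> 512 are
        the two full-scale versions; small values give desk-scale models).
    input_size : int
        Square input size in pixels; must be divisible by 2**(levels-1).
    levels : int
        U-Net depth (5 in the full-scale model).
    learning_rate, epochs, batch_size : Adam step size and schedule.
    dropout_contracting, dropout_expanding : dropout rates per path family.
    smooth : soft-Dice smoothing constant of the loss.
    relu_levels : levels using ReLU; the rest use ELU.
    seed : drives weight init, batch shuffling, and dropout masks.
    """

    def __init__(
        self,
        variant: str = "compound",
        base_filters: int = 64,
        input_size: int = 256,
        levels: int = 5,
        learning_rate: float = 1e-5,
        epochs: int = 10,
        batch_size: int = 8,
        dropout_contracting: float = 0.5,
        dropout_expanding: float = 0.4,
        smooth: float = 1.0,
        relu_levels: tuple = (4, 5),
        threshold: float = 0.5,
        seed: int = 0,
    ) -> None:
        self.variant = variant
        self.base_filters = base_filters
        self.input_size = input_size
        self.levels = levels
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.dropout_contracting = dropout_contracting
        self.dropout_expanding = dropout_expanding
        self.smooth = smooth
        self.relu_levels = relu_levels
        self.threshold = threshold
        self.seed = seed

    # -- helpers ----------------------------------------------------------

    def _build_graph(self):
        return build_wnet(
            self.variant,
            base_filters=self.base_filters,
            input_size=self.input_size,
            levels=self.levels,
            dropout_contracting=self.dropout_contracting,
            dropout_expanding=self.dropout_expanding,
            relu_levels=self.relu_levels,
        )

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 4 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 3:
            raise ValueError(f"X must have shape (n, h, w), got {X.shape}")
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ValueError(
                f"slices are {X.shape[1:]}, model expects "
                f"({self.input_size}, {self.input_size})"
            )
        if X.max() > 1.5:
            X = X / np.float32(255.0)
        return X[:, None]

    def _validate_y(self, y, n: int) -> np.ndarray:
        y = np.asarray(y, dtype=np.float32)
        if y.ndim == 4 and y.shape[1] == 1:
            y = y[:, 0]
        if y.shape != (n, self.input_size, self.input_size):
            raise ValueError(f"y shape {y.shape} does not match X")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("masks must be binary")
        return y[:, None]

    def _mean_dice(self, probs: np.ndarray, y: np.ndarray) -> float:
        return float(
            np.mean(
                [
                    dice_coefficient(p[0], t[0], threshold=self.threshold)
                    for p, t in zip(probs, y)
                ]
            )
        )

    def _eval_forward(self, X: np.ndarray) -> np.ndarray:
        out = []
        for start in range(0, len(X), max(1, self.batch_size)):
            probs, _ = nn.forward(
                self.graph_, self.params_, X[start:start + self.batch_size],
                training=False, order=self._order_,
            )
            out.append(probs)
        return np.concatenate(out, axis=0)

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y, validation_data=None):
        """Train on slices/masks; optional ``validation_data=(Xv, yv)``."""
        X = self._validate_X(X)
        y = self._validate_y(y, len(X))
        if validation_data is not None:
            Xv = self._validate_X(validation_data[0])
            yv = self._validate_y(validation_data[1], len(Xv))
        self.graph_ = self._build_graph()
        self._order_ = self.graph_.topological_order()
        rng = np.random.default_rng(self.seed)
        self.params_ = nn.init_params(self.graph_, rng)
        opt = nn.Adam(learning_rate=self.learning_rate)
        self.history_ = TrainHistory()
        n = len(X)
        bs = max(1, min(self.batch_size, n))
        for _ in range(self.epochs):
            perm = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, bs):
                idx = perm[start:start + bs]
                xb, yb = X[idx], y[idx]
                probs, cache = nn.forward(
                    self.graph_, self.params_, xb, training=True, rng=rng,
                    order=self._order_,
                )
                values, grad = soft_dice_with_grad(probs, yb, self.smooth)
                loss = float(1.0 - values.mean())
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite Dice loss at step {opt.t + 1}"
                    )
                dprobs = -grad / len(xb)
                grads = nn.backward(self.graph_, self.params_, cache, dprobs)
                opt.step(self.params_, grads)
                epoch_losses.append(loss)
            self.history_.loss.append(float(np.mean(epoch_losses)))
            self.history_.train_dice.append(
                self._mean_dice(self._eval_forward(X), y)
            )
            if validation_data is not None:
                pv = self._eval_forward(Xv)
                vvals, _ = soft_dice_with_grad(pv, yv, self.smooth)
                self.history_.val_loss.append(float(1.0 - vvals.mean()))
                self.history_.val_dice.append(self._mean_dice(pv, yv))
        self.n_features_in_ = self.input_size * self.input_size
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel liver probabilities, shape (n, h, w)."""
        self._check_fitted()
        return self._eval_forward(self._validate_X(X))[:, 0]

    def predict(self, X) -> np.ndarray:
        """Binary masks after thresholding the probabilities."""
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-image Dice at the evaluation threshold."""
        self._check_fitted()
        Xv = self._validate_X(X)
        yv = self._validate_y(y, len(Xv))
        return self._mean_dice(self._eval_forward(Xv), yv)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("WNetSegmenter is not fitted yet; call fit()")


def save_weights(model: WNetSegmenter, path) -> None:
    """Serialise fitted weights + hyperparameters to an .npz file."""
    model._check_fitted()
    arrays = {}
    for nid, pg in model.params_.items():
        for key, arr in pg.items():
            arrays[f"{nid}::{key}"] = arr
    arrays["__meta__"] = np.frombuffer(
        json.dumps(model.get_params()).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_weights(path) -> WNetSegmenter:
    """Rebuild a fitted estimator from :func:`save_weights` output."""
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    meta["relu_levels"] = tuple(meta["relu_levels"])
    model = WNetSegmenter(**meta)
    model.graph_ = model._build_graph()
    model._order_ = model.graph_.topological_order()
    params: dict = {}
    for key in data.files:
        if key == "__meta__":
            continue
        nid, pkey = key.rsplit("::", 1)
        params.setdefault(nid, {})[pkey] = data[key]
    model.params_ = params
    model.history_ = TrainHistory()
    return model
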