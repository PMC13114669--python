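"""Scikit-learn-style estimator facade for the segmentation network.

``NeuralSegmenter`` is the package's primary user-facing API: a
``BaseEstimator`` with ``fit(X, y)`` on arrays of grayscale images and
binary masks, ``predict`` / ``predict_proba`` returning masks and
probability maps, and ``score`` returning the mean Dice coefficient.
It composes with sklearn model selection (``get_params``/``set_params``
follow the sklearn contract); the cross-validation and ablation runners
in :mod:`busseg.training` are thin wrappers around the same machinery.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics as met
from .losses import LossConfig
from .network import MINIATURE, ModelConfig, build_model
from .nn import layers as nn
from .phantom import ImageSample
from .training import TrainConfig, fit_model


class NeuralSegmenter(BaseEstimator):
    """Binary lesion segmentation with the triple-branch network.

    Parameters
    ----------
    model_config : ModelConfig
        Architecture hyperparameters (defaults to the CPU-scale
        miniature configuration).
    train_config : TrainConfig
        Optimization protocol.
    loss_config : LossConfig
        Composite-loss weights.
    validation_fraction : float
        Fraction of ``fit`` data held out for early stopping/selection
        when no explicit validation set is passed.
    seed : int
        Master seed for initialization, shuffling and augmentation.
    """

    def __init__(
        self,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        loss_config: LossConfig | None = None,
        validation_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.model_config = model_config
        self.train_config = train_config
        self.loss_config = loss_config
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _configs(self):
        mc = self.model_config if self.model_config is not None else MINIATURE
        tc = self.train_config if self.train_config is not None else TrainConfig()
        lc = self.loss_config if self.loss_config is not None else LossConfig()
        return mc, tc, lc

    @staticmethod
    def _check_X(X, image_size=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("X must be (n_samples, H, H) square grayscale images")
        if image_size is not None and X.shape[1] != image_size:
            raise ValueError(f"images are {X.shape[1]}px but the model expects {image_size}px")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X, y, X_val=None, y_val=None, log=None):
        mc, tc, lc = self._configs()
        X = self._check_X(X, mc.image_size)
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError("y must be binary masks with the same shape as X")
        mc = replace(mc, seed=int(self.seed))
        tc = replace(tc, seed=int(self.seed))
        if X_val is None:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(X))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        train_s = [ImageSample(image=x, mask=m.astype(np.uint8), id=f"train_{i}") for i, (x, m) in enumerate(zip(X, y))]
        val_s = [ImageSample(image=x, mask=m.astype(np.uint8), id=f"val_{i}") for i, (x, m) in enumerate(zip(X_val, y_val))]
        nn.seed_all(int(self.seed))
        self.model_ = build_model(mc)
        self.history_ = fit_model(self.model_, train_s, val_s, tc, lc, log=log)
        self.n_parameters_ = self.model_.n_parameters()
        self.best_epoch_ = self.history_.best_epoch
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._require_fitted()
        X = self._check_X(X, self.model_.config.image_size)
        return self.model_.predict_proba(X)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean Dice similarity coefficient over the given set."""
        preds = self.predict(X)
        return float(np.mean([met.overlap_metrics(p, t)[0] for p, t in zip(preds, np.asarray(y))]))

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this NeuralSegmenter instance is not fitted yet")
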