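"""scikit-learn style estimators wrapping the unsupervised segmenters.

``WNetSegmenter`` fits a W-Net on a stack of images under the
encoder-weighted schedule (CT-loss by default, soft N-cut for the graph-cut
baseline) and predicts per-pixel label maps; ``FeatureClusteringSegmenter``
runs the per-image CNN feature-clustering method.  Both follow the
fit/predict, ``get_params``/``set_params`` and trailing-underscore
conventions, so they compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import losses
from .cnn_baseline import FeatureCNNConfig, cnn_method_train
from .evaluation import best_label_dice
from .training import EWSchedule, ew_train
from .wnet import WNet, WNetConfig, SHALLOW_FILTERS

__all__ = ["WNetSegmenter", "FeatureClusteringSegmenter"]


def _validate_images(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 3:
        X = X[None]
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError(f"expected images of shape (n, H, W, 3), got {X.shape}")
    if X.min() < 0 or X.max() > 1:
        raise ValueError("pixel values must lie in [0, 1]")
    return X


class WNetSegmenter(BaseEstimator):
    """Unsupervised W-Net segmenter with encoder-weighted training.

    Parameters mirror the training defaults: K=2 classes, i=7 encoder epochs
    per cycle, encoder learning rate 7e-5, full-network rate 1e-3, Adam, and
    up to ``max_epochs`` total epochs with best-confidence model selection.

    Attributes (after ``fit``): ``model_`` (the trained W-Net restored to the
    best-confidence checkpoint), ``trace_`` (the training log), ``best_epoch_``
    and ``best_confidence_``.
    """

    def __init__(self, num_classes: int = 2, filters=SHALLOW_FILTERS,
                 loss: str = "ct", i: int = 7, lr_enc: float = 7e-5,
                 lr_entire: float = 1e-3, max_epochs: int = 500,
                 batch_size: int = 4, tv_weight: float = 1.0,
                 augment: bool = True, pretrain_once: bool = False,
                 affinity=None, random_state: int = 0):
        self.num_classes = num_classes
        self.filters = filters
        self.loss = loss
        self.i = i
        self.lr_enc = lr_enc
        self.lr_entire = lr_entire
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.tv_weight = tv_weight
        self.augment = augment
        self.pretrain_once = pretrain_once
        self.affinity = affinity
        self.random_state = random_state

    def _schedule(self) -> EWSchedule:
        kwargs = dict(i=self.i, lr_enc=self.lr_enc, lr_entire=self.lr_entire,
                      max_epochs=self.max_epochs, batch_size=self.batch_size,
                      tv_weight=self.tv_weight, augment=self.augment,
                      pretrain_once=self.pretrain_once, seed=self.random_state)
        if self.affinity is not None:
            kwargs["affinity"] = self.affinity
        return EWSchedule(**kwargs)

    def fit(self, X, y=None):
        """Train on images ``X`` of shape (n, H, W, 3) in [0, 1]; ``y`` ignored."""
        X = _validate_images(X)
        if self.loss not in ("ct", "soft_ncut"):
            raise ValueError(f"loss must be 'ct' or 'soft_ncut', got {self.loss!r}")
        config = WNetConfig(num_classes=self.num_classes,
                            filters_per_level=tuple(self.filters))
        model = WNet(config, seed=self.random_state)
        self.model_, self.trace_ = ew_train(model, X, self._schedule(), loss_mode=self.loss)
        self.best_epoch_ = self.trace_.best_epoch
        self.best_confidence_ = self.trace_.best_confidence
        self.config_ = config
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Response maps (n, H, W, K) from the best checkpoint."""
        if not hasattr(self, "model_"):
            raise RuntimeError("this WNetSegmenter is not fitted yet")
        return self.model_.encode(_validate_images(X), train=False)

    def predict(self, X) -> np.ndarray:
        """Per-pixel argmax label maps (n, H, W)."""
        return losses.pseudo_mask(self.predict_proba(X))

    def score(self, X, y) -> float:
        """Mean best-label Dice against boolean ground-truth masks ``y``."""
        preds = self.predict(X)
        return float(np.mean([best_label_dice(p, t, self.num_classes)[0]
                              for p, t in zip(preds, y)]))


class FeatureClusteringSegmenter(BaseEstimator):
    """Per-image CNN feature clustering, in the style of sklearn clusterers.

    ``fit`` trains one small CNN per input image and stores the resulting
    label maps in ``labels_``; ``fit_predict`` returns them.
    """

    def __init__(self, m_components: int = 3, channels: int = 100,
                 num_classes: int = 2, n_iter: int = 500,
                 continuity_weight: float = 1.0, learning_rate: float = 0.05,
                 random_state: int = 0):
        self.m_components = m_components
        self.channels = channels
        self.num_classes = num_classes
        self.n_iter = n_iter
        self.continuity_weight = continuity_weight
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _validate_images(X)
        masks, traces = [], []
        for j, img in enumerate(X):
            cfg = FeatureCNNConfig(m_components=self.m_components,
                                   channels=self.channels,
                                   num_classes=self.num_classes,
                                   iterations=self.n_iter,
                                   continuity_weight=self.continuity_weight,
                                   lr=self.learning_rate,
                                   seed=self.random_state + j)
            mask, trace = cnn_method_train(img, cfg)
            masks.append(mask)
            traces.append(trace)
        self.labels_ = np.stack(masks)
        self.traces_ = traces
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def score(self, X, y) -> float:
        """Mean best-label Dice of freshly fitted label maps against ``y``."""
        preds = self.fit_predict(X)
        return float(np.mean([best_label_dice(p, t, self.num_classes)[0]
                              for p, t in zip(preds, y)]))
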