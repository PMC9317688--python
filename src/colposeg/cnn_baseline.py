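"""CNN-based differentiable feature clustering (per-image self-training).

The comparison method: a small fully convolutional network — M repeated
components of [3x3 conv -> ReLU -> batch norm] at constant width, then a 1x1
convolution to K channels normalized by a per-channel batch norm — is trained
*on a single image* for T iterations.  Each iteration takes the argmax of the
normalized response map as a (detached) pseudo segmentation mask and descends
the same cross-entropy + total-variation objective as the CT-loss W-Net
(the loss functions are shared, not re-implemented), so pixel labels and
features are optimized jointly until the labels stabilize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import losses
from .nn import BatchNorm2d, Conv2d, ReLU, Sequential, SGD, ChannelSoftmax

__all__ = [
    "FeatureCNNConfig",
    "FeatureCNN",
    "build_feature_cnn",
    "count_feature_cnn_parameters",
    "cnn_method_train",
    "match_parameter_budget",
]


@dataclass(frozen=True)
class FeatureCNNConfig:
    """M feature-extraction components at a constant channel width, K classes."""

    m_components: int = 3
    channels: int = 100
    num_classes: int = 2
    iterations: int = 500
    continuity_weight: float = 1.0
    lr: float = 0.05
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.m_components < 1:
            raise ValueError("m_components must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.continuity_weight < 0:
            raise ValueError("continuity_weight must be >= 0")


class FeatureCNN:
    """Feature extractor + response-map normalization (batch norm over K)."""

    def __init__(self, config: FeatureCNNConfig, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers = []
        ch_in = 3
        for _ in range(config.m_components):
            layers += [Conv2d(ch_in, config.channels, 3, rng=rng, dtype=dtype),
                       ReLU(), BatchNorm2d(config.channels, dtype=dtype)]
            ch_in = config.channels
        layers += [Conv2d(ch_in, config.num_classes, 1, rng=rng, dtype=dtype),
                   BatchNorm2d(config.num_classes, dtype=dtype)]
        self.net = Sequential(*layers)
        self.softmax = ChannelSoftmax()

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Normalized response logits (H, W, K) for one (H, W, 3) image."""
        return self.net.forward(x[None], train=train)[0]

    def backward_from_probs(self, dprobs: np.ndarray) -> None:
        self.net.backward(self.softmax.backward(dprobs[None]))


def build_feature_cnn(config: FeatureCNNConfig, dtype=np.float32) -> FeatureCNN:
    """Seeded construction; identical configs give identical parameters."""
    return FeatureCNN(config, dtype=dtype)


def count_feature_cnn_parameters(config: FeatureCNNConfig) -> int:
    return sum(p.size for p in FeatureCNN(config).params())


def cnn_method_train(image: np.ndarray, config: FeatureCNNConfig):
    """Self-train on one image; returns (pseudo mask, per-iteration trace).

    The trace records loss and the number of distinct labels per iteration;
    collapsing to a single label before T/10 iterations raises a warning that
    is also flagged in the trace.
    """
    x = np.asarray(image, dtype=np.float32)
    if x.ndim != 3 or x.shape[-1] != 3:
        raise ValueError("cnn_method_train expects a single (H, W, 3) image")
    model = FeatureCNN(config)
    opt = SGD(model.params(), lr=config.lr, momentum=config.momentum)
    rows = []
    collapse_warned = False
    pseudo = None
    for t in range(config.iterations):
        logits = model.forward(x, train=True)
        probs = model.softmax.forward(logits[None], train=True)[0]
        pseudo = losses.pseudo_mask(probs)
        n_labels = int(np.unique(pseudo).size)
        value = losses.cross_entropy_loss(probs, pseudo, reduction="mean") \
            + config.continuity_weight * losses.total_variation_loss(probs, reduction="mean")
        grad = losses.cross_entropy_grad(probs, pseudo, reduction="mean") \
            + config.continuity_weight * losses.total_variation_grad(probs, reduction="mean")
        opt.zero_grad()
        model.backward_from_probs(grad.astype(probs.dtype))
        opt.step()
        collapsed_early = n_labels == 1 and t < config.iterations // 10
        if collapsed_early and not collapse_warned:
            warnings.warn(f"label collapse to 1 class at iteration {t}", stacklevel=2)
            collapse_warned = True
        rows.append({"iteration": t, "loss": value, "n_labels": n_labels,
                     "collapsed_early": collapsed_early})
    # final labels from the updated parameters, inference mode
    logits = model.forward(x, train=False)
    probs = model.softmax.forward(logits[None], train=False)[0]
    pseudo = losses.pseudo_mask(probs)
    return pseudo, pd.DataFrame(rows)


def match_parameter_budget(target_count: int, channels: int = 100,
                           num_classes: int = 2, max_m: int = 64) -> FeatureCNNConfig:
    """Config whose component count M best matches a parameter budget.

    Scans M in [1, max_m]; ties resolve to the smaller M.  A budget below the
    single-component model is unreachable and raises, reporting the closest
    achievable count.
    """
    c1 = count_feature_cnn_parameters(
        FeatureCNNConfig(m_components=1, channels=channels, num_classes=num_classes))
    c2 = count_feature_cnn_parameters(
        FeatureCNNConfig(m_components=2, channels=channels, num_classes=num_classes))
    step = c2 - c1  # every component beyond the first adds the same count
    if target_count < c1:
        raise ValueError(
            f"target {target_count} below the minimum model size; "
            f"closest achievable count is {c1} (M=1)")
    best_m, best_gap = None, None
    for m in range(1, max_m + 1):
        gap = abs(c1 + (m - 1) * step - target_count)
        if best_gap is None or gap < best_gap:
            best_m, best_gap = m, gap
    return FeatureCNNConfig(m_components=best_m, channels=channels, num_classes=num_classes)
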