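"""Encoder-weighted (EW) training of the W-Net, plus preprocessing/augmentation.

The schedule repeats cycles of ``i`` encoder-only epochs minimizing the
encoder objective (CT-loss by default, soft N-cut for the graph-cut baseline)
at a small learning rate, followed by one full-autoencoder epoch minimizing
the mean-squared reconstruction error at a larger rate.  With ``i = 1`` this
degenerates to the classic alternating W-Net procedure.  Training is fully
unsupervised; after every cycle the mean confidence score (average per-pixel
maximum probability) over the un-augmented training images is recorded, and
the parameters with the best confidence seen so far are the ones returned.

Two independent Adam states are kept — one over encoder parameters at
``lr_enc``, one over all parameters at ``lr_entire`` — so the two objectives
do not contaminate each other's moment estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from . import losses
from .losses import AffinityParams
from .nn import Adam
from .wnet import NumericalError, WNet, restore_params, snapshot_params

logger = logging.getLogger(__name__)

__all__ = [
    "EWSchedule",
    "TrainingTrace",
    "preprocess",
    "augment",
    "hflip",
    "vflip",
    "gaussian_blur",
    "ew_train",
    "encoder_epoch",
    "full_epoch",
    "select_best_epoch",
]

ENC, FULL = "ENC", "FULL"


@dataclass(frozen=True)
class EWSchedule:
    """The encoder-weighted training plan.

    ``i`` encoder epochs per cycle (``i = 1`` is the baseline alternation);
    the encoder rate is kept well below the full-network rate so the heavier
    encoder schedule does not unbalance the autoencoder.  ``tv_reduction``
    defaults to ``'mean'`` during training so the objective scale — and hence
    the printed learning rates — transfers across image resolutions.
    """

    i: int = 7
    lr_enc: float = 7e-5
    lr_entire: float = 1e-3
    max_epochs: int = 500
    batch_size: int = 4
    optimizer: str = "adam"
    seed: int = 0
    tv_weight: float = 1.0
    ce_reduction: str = "mean"
    tv_reduction: str = "mean"
    augment: bool = True
    pretrain_once: bool = False
    affinity: AffinityParams = field(default_factory=AffinityParams)

    def __post_init__(self):
        if self.i < 1:
            raise ValueError("i must be >= 1")
        if self.lr_enc <= 0 or self.lr_entire <= 0:
            raise ValueError("learning rates must be positive")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")


@dataclass
class TrainingTrace:
    """What happened during a run: step kinds, losses, confidence, best epoch."""

    schedule_log: list = field(default_factory=list)        # (epoch, ENC|FULL)
    loss_log: list = field(default_factory=list)            # (epoch, kind, mean loss)
    confidence_per_cycle: list = field(default_factory=list)
    cycle_end_epochs: list = field(default_factory=list)
    best_epoch: int = -1
    best_confidence: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        conf = dict(zip(self.cycle_end_epochs, self.confidence_per_cycle))
        rows = [
            {"epoch": e, "step_kind": kind, "loss": loss,
             "mean_confidence": conf.get(e, np.nan)}
            for (e, kind), (_, _, loss) in zip(self.schedule_log, self.loss_log)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing and augmentation
# ---------------------------------------------------------------------------

def preprocess(image, target_size: tuple[int, int]) -> np.ndarray:
    """Load/convert an RGB image, bilinear-resize to (H, W), scale to [0, 1]."""
    if isinstance(image, (str, Path)):
        try:
            pil = Image.open(image).convert("RGB")
        except OSError as exc:
            raise OSError(f"cannot read image file {image!r}: {exc}") from exc
    elif isinstance(image, Image.Image):
        pil = image.convert("RGB")
    else:
        arr = np.asarray(image)
        if arr.dtype != np.uint8:
            arr = (np.clip(arr, 0, 1) * 255).round().astype(np.uint8)
        pil = Image.fromarray(arr).convert("RGB")
    h, w = target_size
    pil = pil.resize((w, h), Image.BILINEAR)
    return (np.asarray(pil, dtype=np.float32) / 255.0)


def hflip(image: np.ndarray) -> np.ndarray:
    return image[:, ::-1, :]


def vflip(image: np.ndarray) -> np.ndarray:
    return image[::-1, :, :]


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return image
    return ndimage.gaussian_filter(image, sigma=(sigma, sigma, 0), mode="nearest")


def augment(image: np.ndarray, rng_seed: int) -> np.ndarray:
    """Random horizontal/vertical flip (p=0.5 each) and Gaussian blur (p=0.5,
    sigma ~ U[0, 1.5]); deterministic given ``rng_seed``; output stays in [0,1]."""
    rng = np.random.default_rng(rng_seed)
    out = image
    if rng.random() < 0.5:
        out = hflip(out)
    if rng.random() < 0.5:
        out = vflip(out)
    if rng.random() < 0.5:
        out = gaussian_blur(out, rng.uniform(0.0, 1.5))
    return np.clip(np.ascontiguousarray(out, dtype=image.dtype), 0.0, 1.0)


# ---------------------------------------------------------------------------
# single epochs (exposed so alternative schedules can be scripted exactly)
# ---------------------------------------------------------------------------

def _encoder_batch_grad(model: WNet, x: np.ndarray, schedule: EWSchedule,
                        loss_mode: str, epoch: int, batch: int):
    resp = model.encode(x, train=True, epoch=epoch, batch=batch)
    if loss_mode == "ct":
        pseudo = losses.pseudo_mask(resp)  # refreshed every step, gradient-detached
        value = losses.ct_loss(resp, pseudo, tv_weight=schedule.tv_weight,
                               ce_reduction=schedule.ce_reduction,
                               tv_reduction=schedule.tv_reduction)
        grad = losses.ct_loss_grad(resp, pseudo, tv_weight=schedule.tv_weight,
                                   ce_reduction=schedule.ce_reduction,
                                   tv_reduction=schedule.tv_reduction)
    elif loss_mode == "soft_ncut":
        vals, grads = [], []
        for j in range(x.shape[0]):
            vals.append(losses.soft_ncut_loss(x[j], resp[j], schedule.affinity))
            grads.append(losses.soft_ncut_grad(x[j], resp[j], schedule.affinity))
        value = float(np.mean(vals))
        grad = np.stack(grads).astype(resp.dtype) / x.shape[0]
    else:
        raise ValueError(f"unknown loss_mode {loss_mode!r}")
    if not np.isfinite(value):
        raise NumericalError(f"non-finite encoder loss {value}", epoch=epoch, batch=batch)
    return value, grad.astype(resp.dtype)


def encoder_epoch(model: WNet, batches, optimizer: Adam, schedule: EWSchedule,
                  loss_mode: str = "ct", epoch: int = 0) -> float:
    """One encoder-only epoch; returns the mean batch loss."""
    vals = []
    for b, x in enumerate(batches):
        value, grad = _encoder_batch_grad(model, x, schedule, loss_mode, epoch, b)
        optimizer.zero_grad()
        model.backward_encoder(grad)
        optimizer.step()
        vals.append(value)
    return float(np.mean(vals))


def full_epoch(model: WNet, batches, optimizer: Adam, schedule: EWSchedule,
               epoch: int = 0) -> float:
    """One full-autoencoder epoch minimizing reconstruction MSE."""
    vals = []
    for b, x in enumerate(batches):
        resp = model.encode(x, train=True, epoch=epoch, batch=b)
        recon = model.reconstruct(resp, train=True)
        value = losses.reconstruction_loss(x, recon)
        if not np.isfinite(value):
            raise NumericalError(f"non-finite reconstruction loss {value}",
                                 epoch=epoch, batch=b)
        optimizer.zero_grad()
        model.backward_full(losses.reconstruction_grad(x, recon).astype(recon.dtype))
        optimizer.step()
        vals.append(value)
    return float(np.mean(vals))


def mean_confidence(model: WNet, images: np.ndarray, batch_size: int = 8) -> float:
    """Mean confidence score over images, in inference mode."""
    scores = []
    for s in range(0, len(images), batch_size):
        resp = model.encode(images[s:s + batch_size], train=False)
        scores.extend(resp.max(axis=-1).mean(axis=(1, 2)).tolist())
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# the EW schedule
# ---------------------------------------------------------------------------

def _step_kind(epoch: int, schedule: EWSchedule) -> str:
    if schedule.pretrain_once:
        return ENC if epoch < schedule.i else FULL
    return ENC if (epoch % (schedule.i + 1)) < schedule.i else FULL


def ew_train(model: WNet, images, schedule: EWSchedule,
             loss_mode: str = "ct") -> tuple[WNet, TrainingTrace]:
    """Train a W-Net under the encoder-weighted schedule.

    ``images`` is a list/array of (H, W, 3) floats in [0, 1].  Returns the
    model restored to the best-confidence checkpoint and the training trace.
    """
    images = np.asarray(images, dtype=model.dtype)
    if images.ndim == 3:
        images = images[None]
    if images.shape[0] == 0:
        raise ValueError("at least one training image is required")

    rng = np.random.default_rng(schedule.seed)
    enc_opt = Adam(model.encoder_params(), lr=schedule.lr_enc)
    full_opt = Adam(model.params(), lr=schedule.lr_entire)
    trace = TrainingTrace()
    n = images.shape[0]
    best_snapshot = None

    for epoch in range(schedule.max_epochs):
        kind = _step_kind(epoch, schedule)
        order = rng.permutation(n)
        if schedule.augment:
            seeds = rng.integers(0, 2 ** 31, size=n)
            pool = np.stack([augment(images[j], int(seeds[j])) for j in order])
        else:
            pool = images[order]
        batches = [pool[s:s + schedule.batch_size]
                   for s in range(0, n, schedule.batch_size)]
        try:
            if kind == ENC:
                loss = encoder_epoch(model, batches, enc_opt, schedule, loss_mode, epoch)
            else:
                loss = full_epoch(model, batches, full_opt, schedule, epoch)
        except NumericalError as exc:
            exc.trace = trace
            raise
        trace.schedule_log.append((epoch, kind))
        trace.loss_log.append((epoch, kind, loss))

        cycle_done = (kind == FULL) or (epoch == schedule.max_epochs - 1)
        if cycle_done:
            conf = mean_confidence(model, images)
            trace.confidence_per_cycle.append(conf)
            trace.cycle_end_epochs.append(epoch)
            if best_snapshot is None or conf > trace.best_confidence:
                trace.best_confidence = conf
                trace.best_epoch = epoch
                best_snapshot = snapshot_params(model)
            logger.debug("epoch %d (%s): loss %.5f confidence %.4f",
                         epoch, kind, loss, conf)

    if best_snapshot is not None:
        restore_params(model, best_snapshot)
    return model, trace


def select_best_epoch(trace) -> int:
    """Index of the maximum mean confidence (earliest on ties).

    Accepts a :class:`TrainingTrace` (returns the index into its per-cycle
    confidence record) or any sequence of confidence values.
    """
    record = trace.confidence_per_cycle if isinstance(trace, TrainingTrace) else list(trace)
    if len(record) == 0:
        raise ValueError("empty confidence record")
    return int(np.argmax(record))
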