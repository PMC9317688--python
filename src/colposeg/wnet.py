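"""The W-Net: two U-Nets in series forming a segmenting autoencoder.

The encoder U-Net maps an RGB image to a K-channel per-pixel softmax response
map (the segmentation); the decoder U-Net maps that probability map back to a
3-channel reconstruction.  The decoder consumes the *soft* map so that
reconstruction gradients reach the encoder during full-network updates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import ChannelSoftmax, UNet, BatchNorm2d

__all__ = [
    "WNetConfig",
    "WNet",
    "NumericalError",
    "build_wnet",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "BASELINE_FILTERS",
    "SHALLOW_FILTERS",
]

BASELINE_FILTERS = (64, 128, 256, 512)
SHALLOW_FILTERS = (64, 128, 256)

CHECKPOINT_SCHEMA = "colposeg-wnet-checkpoint-1"


class NumericalError(RuntimeError):
    """Raised when a forward pass or loss produces non-finite values."""

    def __init__(self, msg: str, epoch: int | None = None, batch: int | None = None):
        super().__init__(msg)
        self.epoch = epoch
        self.batch = batch


@dataclass(frozen=True)
class WNetConfig:
    """Architecture of one W-Net (both U-Nets share the filter pyramid).

    ``filters_per_level`` must be strictly increasing; its length is the
    depth.  The baseline pyramid is (64, 128, 256, 512); the shallow variant
    used with encoder-weighted learning is (64, 128, 256).
    """

    input_channels: int = 3
    num_classes: int = 2
    filters_per_level: tuple[int, ...] = SHALLOW_FILTERS
    convs_per_block: int = 2
    kernel_size: int = 3

    def __post_init__(self):
        f = tuple(self.filters_per_level)
        object.__setattr__(self, "filters_per_level", f)
        if len(f) < 2:
            raise ValueError("need at least 2 levels of filters")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError(f"filters_per_level must be strictly increasing, got {f}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")

    @property
    def depth(self) -> int:
        return len(self.filters_per_level)

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.depth - 1)


class WNet:
    """Encoder U-Net + per-pixel softmax + decoder U-Net."""

    def __init__(self, config: WNetConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.encoder = UNet(config.input_channels, config.num_classes,
                            config.filters_per_level, convs_per_block=config.convs_per_block,
                            kernel_size=config.kernel_size, rng=rng, dtype=dtype)
        self.softmax = ChannelSoftmax()
        self.decoder = UNet(config.num_classes, config.input_channels,
                            config.filters_per_level, convs_per_block=config.convs_per_block,
                            kernel_size=config.kernel_size, rng=rng, dtype=dtype)

    # -- parameter access ---------------------------------------------------
    def encoder_params(self):
        return self.encoder.params()

    def decoder_params(self):
        return self.decoder.params()

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def _bn_layers(self):
        out = []
        for net in (self.encoder, self.decoder):
            for blk in net.down_blocks + net.up_blocks:
                out.extend(l for l in blk.layers if isinstance(l, BatchNorm2d))
        return out

    # -- forward / backward -------------------------------------------------
    def encode(self, image: np.ndarray, train: bool = False,
               epoch: int | None = None, batch: int | None = None) -> np.ndarray:
        """Image (H,W,3) or batch (N,H,W,3) -> response map(s) summing to 1."""
        x = np.asarray(image, dtype=self.dtype)
        single = x.ndim == 3
        if single:
            x = x[None]
        logits = self.encoder.forward(x, train=train)
        resp = self.softmax.forward(logits, train=train)
        if not np.all(np.isfinite(resp)):
            raise NumericalError("non-finite values in response map", epoch=epoch, batch=batch)
        return resp[0] if single else resp

    def reconstruct(self, response: np.ndarray, train: bool = False) -> np.ndarray:
        """Response map(s) -> 3-channel reconstruction of the input image."""
        r = np.asarray(response, dtype=self.dtype)
        single = r.ndim == 3
        if single:
            r = r[None]
        if r.shape[-1] != self.config.num_classes:
            raise ValueError(
                f"response has {r.shape[-1]} classes, model expects {self.config.num_classes}")
        out = self.decoder.forward(r, train=train)
        return out[0] if single else out

    def backward_encoder(self, dresponse: np.ndarray) -> None:
        """Backprop a response-map gradient through softmax and encoder."""
        self.encoder.backward(self.softmax.backward(dresponse))

    def backward_full(self, dreconstruction: np.ndarray) -> None:
        """Backprop a reconstruction gradient through the whole W-Net."""
        dresp = self.decoder.backward(dreconstruction)
        self.backward_encoder(dresp)


def build_wnet(config: WNetConfig, seed: int = 0, dtype=np.float32) -> WNet:
    """Construct a W-Net; identical (config, seed) give identical parameters."""
    return WNet(config, seed=seed, dtype=dtype)


def count_parameters(config: WNetConfig) -> int:
    """Exact number of learnable scalars of the W-Net built from ``config``."""
    return sum(p.size for p in WNet(config, seed=0).params())


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: WNet, epoch: int = 0,
                    confidence_trace=None) -> None:
    """Serialize config + parameters + epoch + confidence trace to one file."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params())}
    for i, bn in enumerate(model._bn_layers()):
        arrays[f"bn_{i}_mean"] = bn.running_mean
        arrays[f"bn_{i}_var"] = bn.running_var
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": asdict(model.config),
        "seed": model.seed,
        "epoch": int(epoch),
    }
    trace = np.asarray([] if confidence_trace is None else confidence_trace, dtype=np.float64)
    np.savez(path, __meta__=json.dumps(meta), __confidence__=trace, **arrays)


def load_checkpoint(path) -> tuple[WNet, dict]:
    """Rebuild a W-Net from a checkpoint file; returns (model, metadata)."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unrecognised checkpoint schema: {meta.get('schema')!r}")
        cfg = meta["config"]
        cfg["filters_per_level"] = tuple(cfg["filters_per_level"])
        config = WNetConfig(**cfg)
        model = WNet(config, seed=meta.get("seed", 0))
        params = model.params()
        for i, p in enumerate(params):
            p.data = data[f"param_{i}"].astype(p.data.dtype)
        for i, bn in enumerate(model._bn_layers()):
            bn.running_mean = data[f"bn_{i}_mean"]
            bn.running_var = data[f"bn_{i}_var"]
        meta["confidence_trace"] = data["__confidence__"].tolist()
    return model, meta


def snapshot_params(model: WNet) -> list[np.ndarray]:
    """Copies of all parameter arrays plus batch-norm running statistics."""
    arrs = [p.data.copy() for p in model.params()]
    for bn in model._bn_layers():
        arrs.append(bn.running_mean.copy())
        arrs.append(bn.running_var.copy())
    return arrs


def restore_params(model: WNet, arrays: list[np.ndarray]) -> None:
    params = model.params()
    for p, a in zip(params, arrays):
        p.data = a.copy()
    rest = arrays[len(params):]
    for bn, (m, v) in zip(model._bn_layers(), zip(rest[0::2], rest[1::2])):
        bn.running_mean = m.copy()
        bn.running_var = v.copy()
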