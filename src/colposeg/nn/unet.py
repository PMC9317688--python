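"""U-Net built from the primitive layers, with explicit forward/backward.

Each resolution level is ``[conv 3x3 -> batch norm -> ReLU] x convs_per_block``;
levels are joined by 2x2 max pooling on the way down and learnable 2x2
transposed convolutions plus channel-concatenation skips on the way up.  The
deepest filter count is the bottleneck; a final 1x1 convolution maps to the
requested number of output channels.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Layer,
    MaxPool2d,
    ReLU,
    Sequential,
)

__all__ = ["UNet", "conv_block"]


def conv_block(in_ch: int, out_ch: int, n_convs: int, kernel_size: int, *,
               rng: np.random.Generator, dtype) -> Sequential:
    layers: list[Layer] = []
    ch = in_ch
    for _ in range(n_convs):
        layers += [Conv2d(ch, out_ch, kernel_size, rng=rng, dtype=dtype),
                   BatchNorm2d(out_ch, dtype=dtype), ReLU()]
        ch = out_ch
    return Sequential(*layers)


class UNet(Layer):
    """Encoder-decoder with skip connections; output is linear (no activation)."""

    def __init__(self, in_ch: int, out_ch: int, filters, *, convs_per_block: int = 2,
                 kernel_size: int = 3, rng: np.random.Generator, dtype=np.float32):
        filters = list(filters)
        if len(filters) < 2:
            raise ValueError("U-Net needs at least 2 resolution levels")
        if any(b <= a for a, b in zip(filters, filters[1:])):
            raise ValueError(f"filters must be strictly increasing, got {filters}")
        self.filters = filters
        self.depth = len(filters)
        self.in_ch = in_ch
        self.out_ch = out_ch

        self.down_blocks = []
        ch = in_ch
        for f in filters:
            self.down_blocks.append(conv_block(ch, f, convs_per_block, kernel_size,
                                               rng=rng, dtype=dtype))
            ch = f
        self.pools = [MaxPool2d() for _ in range(self.depth - 1)]
        self.up_convs = []
        self.up_blocks = []
        for j in range(self.depth - 2, -1, -1):
            self.up_convs.append(ConvTranspose2d(filters[j + 1], filters[j], rng=rng, dtype=dtype))
            self.up_blocks.append(conv_block(2 * filters[j], filters[j], convs_per_block,
                                             kernel_size, rng=rng, dtype=dtype))
        self.head = Conv2d(filters[0], out_ch, 1, rng=rng, dtype=dtype)

    def params(self):
        out = []
        for blk in self.down_blocks:
            out.extend(blk.params())
        for up, blk in zip(self.up_convs, self.up_blocks):
            out.extend(up.params())
            out.extend(blk.params())
        out.extend(self.head.params())
        return out

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        stride = 2 ** (self.depth - 1)
        if h % stride or w % stride:
            raise ValueError(
                f"input {h}x{w} not divisible by the down-sampling factor {stride}")
        skips = []
        for j, blk in enumerate(self.down_blocks):
            x = blk.forward(x, train=train)
            if j < self.depth - 1:
                skips.append(x)
                x = self.pools[j].forward(x, train=train)
        self._skip_ch = [s.shape[-1] for s in skips] if train else None
        for up, blk, skip in zip(self.up_convs, self.up_blocks, reversed(skips)):
            x = up.forward(x, train=train)
            x = np.concatenate([skip, x], axis=-1)
            x = blk.forward(x, train=train)
        return self.head.forward(x, train=train)

    def backward(self, dy):
        dy = self.head.backward(dy)
        # walk the up path in reverse; dskips[j] collects the gradient for skips[j]
        dskips = [None] * (self.depth - 1)
        for idx in range(len(self.up_blocks) - 1, -1, -1):
            dy = self.up_blocks[idx].backward(dy)
            j_skip = self.depth - 2 - idx
            sc = self._skip_ch[j_skip]
            dskips[j_skip], dy = dy[..., :sc], dy[..., sc:]
            dy = self.up_convs[idx].backward(dy)
        for j in range(self.depth - 1, -1, -1):
            if j < self.depth - 1:
                dy = self.pools[j].backward(dy)
                dy = dy + dskips[j]
            dy = self.down_blocks[j].backward(dy)
        return dy
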