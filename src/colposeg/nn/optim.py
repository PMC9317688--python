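"""Gradient-descent optimizers operating on lists of :class:`Param`."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam", "SGD", "zero_grads"]


def zero_grads(params: list[Param]) -> None:
    for p in params:
        p.grad[...] = 0


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        zero_grads(self.params)


class SGD:
    """Plain SGD with optional classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.vel = [np.zeros_like(p.data) for p in params] if momentum else None

    def step(self) -> None:
        if self.vel is None:
            for p in self.params:
                p.data -= (self.lr * p.grad).astype(p.data.dtype)
            return
        for p, v in zip(self.params, self.vel):
            v *= self.momentum
            v += p.grad
            p.data -= (self.lr * v).astype(p.data.dtype)

    def zero_grad(self) -> None:
        zero_grads(self.params)
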