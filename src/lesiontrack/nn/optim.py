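"""Adam optimiser over :class:`~lesiontrack.nn.layers.Param` lists."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
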