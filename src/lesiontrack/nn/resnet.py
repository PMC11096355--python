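"""Residual CNN encoders emitting one feature vector per input image.

The layout mirrors the standard 34-layer residual network: 7-wide
stride-2 stem, 3x3 max-pool, four stages of basic blocks with channel
doubling and stride-2 downsampling, global average pooling and a final
linear projection to ``feature_dim``.  ``EncoderConfig.width`` scales all
channel counts; ``blocks`` sets the per-stage depth, so a quarter-width
(1,1,1,1) desk encoder and the full-scale (3,4,6,3) encoder share every
code path.
"""

from __future__ import annotations

import numpy as np

from ..config import EncoderConfig
from .layers import (
    BasicBlock,
    BatchNorm,
    Conv,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool,
    ReLU,
    Sequential,
)


class ResNetEncoder(Layer):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        ndim = 2 if config.dims == "2d" else 3
        self.ndim = ndim
        chans = config.stage_channels
        self.stem = Sequential(
            Conv(config.in_channels, chans[0], 7, 2, 3, ndim=ndim, rng=rng),
            BatchNorm(chans[0], ndim=ndim),
            ReLU(),
            MaxPool(3, 2, 1, ndim=ndim),
        )
        blocks = []
        in_ch = chans[0]
        for stage, (c, n_blocks) in enumerate(zip(chans, config.blocks)):
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                blocks.append(BasicBlock(in_ch, c, stride, ndim=ndim, rng=rng))
                in_ch = c
        self.blocks = Sequential(*blocks)
        self.gap = GlobalAvgPool()
        self.fc = Linear(in_ch, config.feature_dim, rng=rng)
        self.last_activation: np.ndarray | None = None

    @property
    def feature_dim(self) -> int:
        return self.config.feature_dim

    def params(self):
        return self.stem.params() + self.blocks.params() + self.fc.params()

    def forward(self, x, train=False, keep_activation=False):
        expected = (self.config.in_channels,) + tuple(self.config.input_shape)
        if x.ndim != self.ndim + 2 or x.shape[1:] != expected:
            raise ValueError(
                f"encoder expects input of shape (N, {', '.join(map(str, expected))}), "
                f"got {x.shape}"
            )
        h = self.stem.forward(x, train)
        h = self.blocks.forward(h, train)
        if keep_activation:
            self.last_activation = h.copy()
        h = self.gap.forward(h, train)
        return self.fc.forward(h, train)

    def backward(self, grad):
        g = self.fc.backward(grad)
        g = self.gap.backward(g)
        g = self.blocks.backward(g)
        return self.stem.backward(g)


def encode(images: np.ndarray, encoder: ResNetEncoder, batch: int = 32) -> np.ndarray:
    """Deterministic (eval-mode) features for a stack of images."""
    outs = [
        encoder.forward(images[i : i + batch].astype(np.float32), train=False)
        for i in range(0, len(images), batch)
    ]
    return np.concatenate(outs, axis=0)
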