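"""Sequence heads over per-timepoint feature vectors.

Two heads are provided: a fixed-length concatenation head (all timepoint
features concatenated into one fully connected layer — e.g. 4 x 512 =
2048 inputs at full scale) and a gated recurrent unit head whose final
hidden state feeds a linear output layer and which accepts any sequence
length from one to four scans.
"""

from __future__ import annotations

import math

import numpy as np

from .layers import Layer, Linear, Param


class GRUCell(Layer):
    """Single-layer GRU with the standard reset/update/candidate gating.

    Gate order in the stacked weights is (r, z, n):
    r = sigmoid(Wi_r x + bi_r + Wh_r h + bh_r),
    z likewise, n = tanh(Wi_n x + bi_n + r * (Wh_n h + bh_n)),
    h' = (1 - z) n + z h.
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        bound = 1.0 / math.sqrt(hidden_dim)
        u = lambda shape: rng.uniform(-bound, bound, size=shape).astype(np.float32)
        self.Wi = Param(u((3 * hidden_dim, input_dim)))
        self.Wh = Param(u((3 * hidden_dim, hidden_dim)))
        self.bi = Param(np.zeros(3 * hidden_dim, dtype=np.float32))
        self.bh = Param(np.zeros(3 * hidden_dim, dtype=np.float32))

    def params(self):
        return [self.Wi, self.Wh, self.bi, self.bh]

    def _split(self, m):
        h = self.hidden_dim
        return m[:h], m[h : 2 * h], m[2 * h :]

    def forward(self, x_seq: np.ndarray, train: bool = False) -> np.ndarray:
        """x_seq (N, T, input_dim) -> final hidden state (N, hidden_dim)."""
        if x_seq.ndim != 3 or x_seq.shape[2] != self.input_dim:
            raise ValueError(
                f"expected (N, T, {self.input_dim}) feature sequence, got {x_seq.shape}"
            )
        n, t, _ = x_seq.shape
        if t < 1:
            raise ValueError("empty sequence")
        h = np.zeros((n, self.hidden_dim), dtype=np.float32)
        wir, wiz, win = self._split(self.Wi.value)
        whr, whz, whn = self._split(self.Wh.value)
        bir, biz, bin_ = self._split(self.bi.value)
        bhr, bhz, bhn = self._split(self.bh.value)
        self._cache = []
        for step in range(t):
            x = x_seq[:, step]
            r = _sigmoid(x @ wir.T + bir + h @ whr.T + bhr)
            z = _sigmoid(x @ wiz.T + biz + h @ whz.T + bhz)
            hn = h @ whn.T + bhn
            cand = np.tanh(x @ win.T + bin_ + r * hn)
            h_new = (1.0 - z) * cand + z * h
            self._cache.append((x, h, r, z, cand, hn))
            h = h_new
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        wir, wiz, win = self._split(self.Wi.value)
        whr, whz, whn = self._split(self.Wh.value)
        t = len(self._cache)
        n = dh.shape[0]
        dx_seq = np.zeros((n, t, self.input_dim), dtype=np.float32)
        h_dim = self.hidden_dim
        for step in reversed(range(t)):
            x, h_prev, r, z, cand, hn = self._cache[step]
            dz = dh * (h_prev - cand)
            dcand = dh * (1.0 - z)
            dh_prev = dh * z
            dcand_pre = dcand * (1.0 - cand**2)
            dr = dcand_pre * hn
            dhn = dcand_pre * r
            dr_pre = dr * r * (1.0 - r)
            dz_pre = dz * z * (1.0 - z)
            self.Wi.grad[:h_dim] += dr_pre.T @ x
            self.Wi.grad[h_dim : 2 * h_dim] += dz_pre.T @ x
            self.Wi.grad[2 * h_dim :] += dcand_pre.T @ x
            self.bi.grad[:h_dim] += dr_pre.sum(axis=0)
            self.bi.grad[h_dim : 2 * h_dim] += dz_pre.sum(axis=0)
            self.bi.grad[2 * h_dim :] += dcand_pre.sum(axis=0)
            self.Wh.grad[:h_dim] += dr_pre.T @ h_prev
            self.Wh.grad[h_dim : 2 * h_dim] += dz_pre.T @ h_prev
            self.Wh.grad[2 * h_dim :] += dhn.T @ h_prev
            self.bh.grad[:h_dim] += dr_pre.sum(axis=0)
            self.bh.grad[h_dim : 2 * h_dim] += dz_pre.sum(axis=0)
            self.bh.grad[2 * h_dim :] += dhn.sum(axis=0)
            dh_prev = dh_prev + dr_pre @ whr + dz_pre @ whz + dhn @ whn
            dx_seq[:, step] = dr_pre @ wir + dz_pre @ wiz + dcand_pre @ win
            dh = dh_prev
        self._cache = []
        return dx_seq


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class GRUHead(Layer):
    """GRU over the timepoint sequence; final hidden state -> linear logit."""

    def __init__(self, feature_dim: int, hidden_dim: int | None = None, rng=None):
        hidden_dim = hidden_dim or feature_dim
        self.cell = GRUCell(feature_dim, hidden_dim, rng=rng)
        self.out = Linear(hidden_dim, 1, rng=rng)

    def params(self):
        return self.cell.params() + self.out.params()

    def forward(self, feats: np.ndarray, train: bool = False) -> np.ndarray:
        """feats (N, T, feature_dim), any T >= 1 -> logits (N,)."""
        h = self.cell.forward(feats, train)
        return self.out.forward(h, train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.out.backward(dlogits[:, None])
        return self.cell.backward(dh)


class ConcatHead(Layer):
    """Concatenate a fixed number of timepoint features into one FC layer."""

    def __init__(self, n_timepoints: int, feature_dim: int, rng=None):
        self.n_timepoints = n_timepoints
        self.feature_dim = feature_dim
        self.fc = Linear(n_timepoints * feature_dim, 1, rng=rng)

    @property
    def input_dim(self) -> int:
        return self.n_timepoints * self.feature_dim

    def params(self):
        return self.fc.params()

    def forward(self, feats: np.ndarray, train: bool = False) -> np.ndarray:
        if feats.ndim != 3 or feats.shape[1] != self.n_timepoints:
            raise ValueError(
                f"concatenation head was built for exactly {self.n_timepoints} "
                f"timepoints, got input of shape {feats.shape}"
            )
        self._n = feats.shape[0]
        return self.fc.forward(feats.reshape(self._n, -1), train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.fc.backward(dlogits[:, None])
        return g.reshape(self._n, self.n_timepoints, self.feature_dim)
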