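"""Minimal dense/convolutional layer library with explicit backprop.

Everything is plain float32 numpy.  Each layer caches what its most
recent forward pass needs for the matching backward pass, so the usage
contract is strictly forward-then-backward per batch.  Convolutions are
dimension-generic (2D and 3D) via im2col built on
``numpy.lib.stride_tricks.sliding_window_view``; the col2im scatter uses
precomputed flat index maps cached per input geometry.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _as_tuple(v, n):
    return tuple(v) if isinstance(v, (tuple, list)) else (v,) * n


def _im2col_geometry(spatial, ksize, stride):
    """Output spatial shape plus (L, K) absolute-position index map."""
    out_shape = tuple(
        (s - k) // st + 1 for s, k, st in zip(spatial, ksize, stride)
    )
    out_starts = [np.arange(o) * st for o, st in zip(out_shape, stride)]
    kern = [np.arange(k) for k in ksize]
    ndim = len(spatial)
    om = np.stack(np.meshgrid(*out_starts, indexing="ij"), axis=-1).reshape(-1, ndim)
    km = np.stack(np.meshgrid(*kern, indexing="ij"), axis=-1).reshape(-1, ndim)
    abs_pos = om[:, None, :] + km[None, :, :]  # (L, K, ndim)
    flat = np.ravel_multi_index(
        tuple(abs_pos[..., a] for a in range(ndim)), spatial
    )
    return out_shape, flat  # flat: (L, K) indices into flattened spatial grid


class Conv(Layer):
    """N-dimensional convolution (cross-correlation), no bias (BN follows)."""

    def __init__(self, in_ch, out_ch, ksize, stride=1, pad=0, ndim=2, rng=None):
        self.ndim = ndim
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.ksize = _as_tuple(ksize, ndim)
        self.stride = _as_tuple(stride, ndim)
        self.pad = _as_tuple(pad, ndim)
        fan_in = in_ch * math.prod(self.ksize)
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, math.sqrt(2.0 / fan_in),
                                  size=(out_ch, fan_in)).astype(np.float32))
        self._geom_cache: dict = {}

    def params(self):
        return [self.W]

    def _geometry(self, padded_spatial):
        key = padded_spatial
        if key not in self._geom_cache:
            self._geom_cache[key] = _im2col_geometry(
                padded_spatial, self.ksize, self.stride
            )
        return self._geom_cache[key]

    def forward(self, x, train=False):
        if x.ndim != self.ndim + 2 or x.shape[1] != self.in_ch:
            raise ValueError(
                f"expected input (N, {self.in_ch}, {'x'.join('S' * self.ndim)}), got {x.shape}"
            )
        n = x.shape[0]
        pad_width = [(0, 0), (0, 0)] + [(p, p) for p in self.pad]
        xp = np.pad(x, pad_width)
        self._padded_spatial = xp.shape[2:]
        out_shape, flat = self._geometry(self._padded_spatial)
        win = sliding_window_view(xp, self.ksize, axis=tuple(range(2, 2 + self.ndim)))
        # win: (N, C, *Of, *k) -> subsample strides -> (N, C, *O, *k)
        sl = (slice(None), slice(None)) + tuple(
            slice(None, None, st) for st in self.stride
        ) + (slice(None),) * self.ndim
        win = win[sl]
        # -> (N, *O, C, *k) -> (N, L, C*K)
        axes = (0,) + tuple(range(2, 2 + self.ndim)) + (1,) + tuple(
            range(2 + self.ndim, 2 + 2 * self.ndim)
        )
        cols = np.ascontiguousarray(win.transpose(axes)).reshape(
            n, -1, self.in_ch * math.prod(self.ksize)
        )
        self._cols = cols
        self._out_shape = out_shape
        out = cols @ self.W.value.T  # (N, L, oc)
        return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(
            n, self.out_ch, *out_shape
        )

    def backward(self, grad):
        n = grad.shape[0]
        L = self._cols.shape[1]
        g2 = np.ascontiguousarray(
            grad.reshape(n, self.out_ch, L).transpose(0, 2, 1)
        )  # (N, L, oc)
        self.W.grad += np.tensordot(g2, self._cols, axes=([0, 1], [0, 1]))
        dcols = g2 @ self.W.value  # (N, L, CK)
        _, flat = self._geometry(self._padded_spatial)
        K = math.prod(self.ksize)
        P = math.prod(self._padded_spatial)
        # cols layout per l: channel-major then kernel offset
        idx = (
            np.arange(self.in_ch)[None, :, None] * P + flat[:, None, :]
        ).reshape(L, self.in_ch * K)
        dxp = np.empty((n, self.in_ch * P), dtype=np.float32)
        flat_idx = idx.ravel()
        for i in range(n):
            dxp[i] = np.bincount(
                flat_idx, weights=dcols[i].ravel(), minlength=self.in_ch * P
            )
        dxp = dxp.reshape(n, self.in_ch, *self._padded_spatial)
        sl = (slice(None), slice(None)) + tuple(
            slice(p, s - p) for p, s in zip(self.pad, self._padded_spatial)
        )
        self._cols = None
        return np.ascontiguousarray(dxp[sl])


class MaxPool(Layer):
    def __init__(self, ksize=3, stride=2, pad=1, ndim=2):
        self.ndim = ndim
        self.ksize = _as_tuple(ksize, ndim)
        self.stride = _as_tuple(stride, ndim)
        self.pad = _as_tuple(pad, ndim)
        self._geom_cache: dict = {}

    def _geometry(self, padded_spatial):
        if padded_spatial not in self._geom_cache:
            self._geom_cache[padded_spatial] = _im2col_geometry(
                padded_spatial, self.ksize, self.stride
            )
        return self._geom_cache[padded_spatial]

    def forward(self, x, train=False):
        n, c = x.shape[:2]
        pad_width = [(0, 0), (0, 0)] + [(p, p) for p in self.pad]
        xp = np.pad(x, pad_width, constant_values=-np.inf)
        self._padded_spatial = xp.shape[2:]
        self._in_spatial = x.shape[2:]
        out_shape, flat = self._geometry(self._padded_spatial)
        win = sliding_window_view(xp, self.ksize, axis=tuple(range(2, 2 + self.ndim)))
        sl = (slice(None), slice(None)) + tuple(
            slice(None, None, st) for st in self.stride
        ) + (slice(None),) * self.ndim
        win = win[sl].reshape(n, c, -1, math.prod(self.ksize))  # (N, C, L, K)
        self._argmax = win.argmax(axis=3)
        out = win.max(axis=3)
        return out.reshape(n, c, *out_shape)

    def backward(self, grad):
        n, c = grad.shape[:2]
        _, flat = self._geometry(self._padded_spatial)
        L = flat.shape[0]
        g = grad.reshape(n, c, L)
        pos = flat[np.arange(L)[None, None, :], self._argmax]  # (N, C, L)
        P = math.prod(self._padded_spatial)
        pos = pos + np.arange(c)[None, :, None] * P
        dxp = np.empty((n, c * P), dtype=np.float32)
        for i in range(n):
            dxp[i] = np.bincount(
                pos[i].ravel(), weights=g[i].ravel().astype(np.float64), minlength=c * P
            )
        dxp = dxp.reshape(n, c, *self._padded_spatial)
        sl = (slice(None), slice(None)) + tuple(
            slice(p, s - p) for p, s in zip(self.pad, self._padded_spatial)
        )
        return np.ascontiguousarray(dxp[sl])


class BatchNorm(Layer):
    def __init__(self, channels, ndim=2, momentum=0.1, eps=1e-5):
        self.ndim = ndim
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=False):
        axes = (0,) + tuple(range(2, x.ndim))
        bs = self._bshape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean.reshape(bs)) / std.reshape(bs)
        self._xhat = xhat
        self._std = std
        self._train = train
        return self.gamma.value.reshape(bs) * xhat + self.beta.value.reshape(bs)

    def backward(self, grad):
        axes = (0,) + tuple(range(2, grad.ndim))
        bs = self._bshape(grad)
        xhat = self._xhat
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value.reshape(bs)
        if not self._train:
            return dxhat / self._std.reshape(bs)
        m = grad.size / grad.shape[1]
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(bs)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(bs)
        )
        self._xhat = None
        return term / self._std.reshape(bs)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, grad):
        return np.where(self._pos, grad, 0.0)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._spatial = x.shape[2:]
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, grad):
        scale = 1.0 / math.prod(self._spatial)
        g = grad.reshape(grad.shape + (1,) * len(self._spatial))
        return np.broadcast_to(g * scale, grad.shape + self._spatial).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_features, out_features, rng=None):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / math.sqrt(in_features)
        self.in_features = in_features
        self.W = Param(
            rng.uniform(-bound, bound, size=(out_features, in_features)).astype(np.float32)
        )
        self.b = Param(np.zeros(out_features, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"expected input with {self.in_features} features, got {x.shape[-1]}"
            )
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad):
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        self._x = None
        return grad @ self.W.value


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class BasicBlock(Layer):
    """Two 3x3 convolutions with identity (or 1x1-projected) skip."""

    def __init__(self, in_ch, out_ch, stride=1, ndim=2, rng=None):
        self.conv1 = Conv(in_ch, out_ch, 3, stride, 1, ndim=ndim, rng=rng)
        self.bn1 = BatchNorm(out_ch, ndim=ndim)
        self.relu1 = ReLU()
        self.conv2 = Conv(out_ch, out_ch, 3, 1, 1, ndim=ndim, rng=rng)
        self.bn2 = BatchNorm(out_ch, ndim=ndim)
        self.relu2 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down: Sequential | None = Sequential(
                Conv(in_ch, out_ch, 1, stride, 0, ndim=ndim, rng=rng),
                BatchNorm(out_ch, ndim=ndim),
            )
        else:
            self.down = None

    def params(self):
        ps = (
            self.conv1.params() + self.bn1.params()
            + self.conv2.params() + self.bn2.params()
        )
        if self.down is not None:
            ps += self.down.params()
        return ps

    def forward(self, x, train=False):
        idn = self.down.forward(x, train) if self.down is not None else x
        y = self.conv1.forward(x, train)
        y = self.bn1.forward(y, train)
        y = self.relu1.forward(y, train)
        y = self.conv2.forward(y, train)
        y = self.bn2.forward(y, train)
        return self.relu2.forward(y + idn, train)

    def backward(self, grad):
        g = self.relu2.backward(grad)
        gm = self.bn2.backward(g)
        gm = self.conv2.backward(gm)
        gm = self.relu1.backward(gm)
        gm = self.bn1.backward(gm)
        gm = self.conv1.backward(gm)
        gs = self.down.backward(g) if self.down is not None else g
        return gm + gs
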