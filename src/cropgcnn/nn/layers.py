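"""Trainable layers with explicit forward/backward passes.

Channels-last layout ``(n, h, w, c)``, float32 arithmetic.  Each layer
exposes ``forward(x, training)``, ``backward(dy)`` and parallel
``params`` / ``grads`` lists of ndarrays (updated in place by the
optimizers).  The grouped convolution here is the fast im2col/GEMM path;
its semantics are pinned down by the naive reference in
:mod:`cropgcnn.gconv` and the two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "GroupedConv2D",
    "BatchNorm2D",
    "ReLU",
    "PReLU",
    "AvgPool2D",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "Dropout",
    "Softmax",
]


class Layer:
    """Base layer: stateless by default, no parameters."""

    name: str = "layer"

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params))


class GroupedConv2D(Layer):
    """Grouped 2-D cross-correlation (im2col + GEMM).

    Input and output channels are split into ``groups`` contiguous blocks;
    output block g convolves only input block g, so the weight tensor has
    shape ``(out_channels, in_channels // groups, kh, kw)`` — a factor
    ``groups`` fewer weights than a full convolution at equal widths.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int] = (3, 3),
        groups: int = 1,
        padding: str = "same",
        bias: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "grouped_conv",
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"groups={groups} must divide in_channels={in_channels} "
                f"and out_channels={out_channels}"
            )
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid': {padding!r}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        self.groups = groups
        self.padding = padding
        self.use_bias = bias
        self.name = name
        cg = in_channels // groups
        kh, kw = self.kernel
        fan_in = cg * kh * kw
        rng = rng or np.random.default_rng()
        # variance-scaling fan-in initialization
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_channels, cg, kh, kw)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._cache = None

    @property
    def params(self):
        return [self.W] + ([self.b] if self.use_bias else [])

    @property
    def grads(self):
        return [self.dW] + ([self.db] if self.use_bias else [])

    def _pad(self, x):
        kh, kw = self.kernel
        if self.padding == "valid":
            return x, (0, 0)
        top, left = (kh - 1) // 2, (kw - 1) // 2
        bottom, right = kh - 1 - top, kw - 1 - left
        return (
            np.pad(x, ((0, 0), (top, bottom), (left, right), (0, 0))),
            (top, left),
        )

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        n = x.shape[0]
        kh, kw = self.kernel
        xp, _ = self._pad(x)
        oh, ow = xp.shape[1] - kh + 1, xp.shape[2] - kw + 1
        cg = self.in_channels // self.groups
        og = self.out_channels // self.groups
        # (n, oh, ow, c, kh, kw)
        view = sliding_window_view(xp, (kh, kw), axis=(1, 2))
        out = np.empty((n, oh, ow, self.out_channels), dtype=np.float32)
        cols_cache = []
        for g in range(self.groups):
            cols = view[:, :, :, g * cg : (g + 1) * cg, :, :].reshape(
                n * oh * ow, cg * kh * kw
            )
            wmat = self.W[g * og : (g + 1) * og].reshape(og, cg * kh * kw).T
            out[..., g * og : (g + 1) * og] = (cols @ wmat).reshape(n, oh, ow, og)
            cols_cache.append(cols)
        if self.use_bias:
            out += self.b
        self._cache = (x.shape, cols_cache)
        return out

    def backward(self, dy):
        x_shape, cols_cache = self._cache
        n, h, w, _ = x_shape
        kh, kw = self.kernel
        cg = self.in_channels // self.groups
        og = self.out_channels // self.groups
        oh, ow = dy.shape[1], dy.shape[2]
        xp_shape = (
            (n, h + kh - 1, w + kw - 1, self.in_channels)
            if self.padding == "same"
            else (n, h, w, self.in_channels)
        )
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for g in range(self.groups):
            dyg = np.ascontiguousarray(
                dy[..., g * og : (g + 1) * og], dtype=np.float32
            ).reshape(n * oh * ow, og)
            cols = cols_cache[g]
            dwmat = cols.T @ dyg  # (cg*kh*kw, og)
            self.dW[g * og : (g + 1) * og] = dwmat.T.reshape(og, cg, kh, kw)
            if self.use_bias:
                self.db[g * og : (g + 1) * og] = dyg.sum(axis=0)
            wmat = self.W[g * og : (g + 1) * og].reshape(og, cg * kh * kw).T
            dcols = (dyg @ wmat.T).reshape(n, oh, ow, cg, kh, kw)
            sl = slice(g * cg, (g + 1) * cg)
            for dyk in range(kh):
                for dxk in range(kw):
                    dxp[:, dyk : dyk + oh, dxk : dxk + ow, sl] += dcols[
                        :, :, :, :, dyk, dxk
                    ]
        if self.padding == "same":
            top, left = (kh - 1) // 2, (kw - 1) // 2
            return dxp[:, top : top + h, left : left + w, :]
        return dxp


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (n, h, w)."""

    def __init__(self, channels, momentum=0.9, eps=1e-5, name="batch_norm"):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        axes = (0, 1, 2)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * invstd
        self._cache = (xhat, invstd, training)
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        xhat, invstd, training = self._cache
        dy = np.asarray(dy, dtype=np.float32)
        axes = (0, 1, 2)
        self.dgamma[...] = np.einsum("nhwc,nhwc->c", dy, xhat)
        self.dbeta[...] = dy.sum(axis=axes)
        if not training:
            return dy * (self.gamma * invstd)
        m = float(np.prod([xhat.shape[i] for i in range(3)]))
        # dxhat = dy * gamma folded into the channel-wise coefficients
        coef = self.gamma * invstd
        return coef * dy - (coef / m) * (
            self.dbeta + xhat * self.dgamma
        )


class ReLU(Layer):
    def __init__(self, name="relu"):
        self.name = name
        self._mask = None

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class PReLU(Layer):
    """Parametric ReLU with one learnable negative-side slope per channel."""

    def __init__(self, channels, init=0.25, name="prelu"):
        self.a = np.full(channels, init, dtype=np.float32)
        self.da = np.zeros_like(self.a)
        self.name = name
        self._cache = None

    @property
    def params(self):
        return [self.a]

    @property
    def grads(self):
        return [self.da]

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        pos = x > 0
        self._cache = (pos, x)
        return np.where(pos, x, self.a * x)

    def backward(self, dy):
        pos, x = self._cache
        dy = np.asarray(dy, dtype=np.float32)
        neg = np.where(pos, np.float32(0.0), x)
        self.da[...] = np.einsum("nhwc,nhwc->c", dy, neg)
        return np.where(pos, dy, self.a * dy)


class AvgPool2D(Layer):
    """2x2 average pooling, stride 2 (spatial dims must be even)."""

    def __init__(self, name="avg_pool"):
        self.name = name
        self._shape = None

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dy):
        n, h, w, c = self._shape
        up = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2)
        return (up / 4.0).astype(np.float32)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; ties share the gradient equally."""

    def __init__(self, name="max_pool"):
        self.name = name
        self._cache = None

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        self._cache = (mask / counts, x.shape)
        return out

    def backward(self, dy):
        weights, (n, h, w, c) = self._cache
        return (weights * dy[:, :, None, :, None, :]).reshape(n, h, w, c)


class Flatten(Layer):
    def __init__(self, name="flatten"):
        self.name = name
        self._shape = None

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features, out_features, rng=None, name="dense"):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(
            0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features)
        ).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.in_features = in_features
        self.out_features = out_features
        self.name = name
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        dy = np.asarray(dy, dtype=np.float32)
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng=None, name="dropout"):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1): {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self.name = name
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Softmax(Layer):
    def __init__(self, name="softmax"):
        self.name = name
        self._p = None

    def forward(self, x, training=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        self._p = p
        return p

    def backward(self, dy):
        p = self._p
        return p * (dy - (dy * p).sum(axis=1, keepdims=True))
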