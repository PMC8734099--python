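"""Minimal NumPy neural-network engine: layers, losses, and Adam.

Implements exactly the operations the gene classifier needs — 3x3
same-padding convolutions, a single 2x2 max pool, a global (adaptive
1x1) max pool, dense layers, ReLU — each with a hand-derived backward
pass, plus softmax cross-entropy, sigmoid cross-entropy on logits, and
the Adam update rule. Activations use a channels-last (B, H, W, C)
layout so the convolution reduces to one GEMM over an im2col buffer.
Everything is float32 and deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Parameter:
    """A weight tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He (Kaiming) uniform init, bound sqrt(6 / fan_in).

    Keeps activation variance roughly constant through deep ReLU stacks,
    which the eight-layer convolution tower needs for usable gradients at
    a small learning rate.
    """
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (spatial-size preserving).

    The kernel is stored as a (9 * C_in, C_out) matrix; rows are ordered
    (offset_row, offset_col, channel).
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * 9
        self.weight = Parameter(he_uniform(rng, (fan_in, out_channels), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE))
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (B, H, W, C, 3, 3)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            B * H * W, 9 * C
        )
        out = cols @ self.weight.value
        out += self.bias.value
        if train:
            self._cache = (cols, (B, H, W, C))
        return out.reshape(B, H, W, self.out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (B, H, W, C) = self._cache
        self._cache = None
        d2 = dout.reshape(B * H * W, self.out_channels)
        self.weight.grad += cols.T @ d2
        self.bias.grad += d2.sum(axis=0)
        dcols = (d2 @ self.weight.value.T).reshape(B, H, W, 3, 3, C)
        dxp = np.zeros((B, H + 2, W + 2, C), dtype=DTYPE)
        for di in range(3):
            for dj in range(3):
                dxp[:, di:di + H, dj:dj + W, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, 1:-1, 1:-1, :]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pool, stride 2. Inputs with a spatial side < 2 pass through
    unchanged (nothing to pool); odd trailing rows/columns are dropped."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        B, H, W, C = x.shape
        if H < 2 or W < 2:
            if train:
                self._cache = ("identity",)
            return x
        H2, W2 = H // 2, W // 2
        blocks = np.ascontiguousarray(
            x[:, : 2 * H2, : 2 * W2, :]
            .reshape(B, H2, 2, W2, 2, C)
            .transpose(0, 1, 3, 5, 2, 4)
        ).reshape(B, H2, W2, C, 4)
        idx = np.argmax(blocks, axis=-1)  # first maximum wins ties
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = ("pool", (B, H, W, C), idx)
        return out

    def backward(self, dout):
        if self._cache[0] == "identity":
            self._cache = None
            return dout
        _, (B, H, W, C), idx = self._cache
        self._cache = None
        H2, W2 = H // 2, W // 2
        dblocks = np.zeros((B, H2, W2, C, 4), dtype=DTYPE)
        np.put_along_axis(dblocks, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((B, H, W, C), dtype=DTYPE)
        dx[:, : 2 * H2, : 2 * W2, :] = (
            dblocks.reshape(B, H2, W2, C, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(B, 2 * H2, 2 * W2, C)
        )
        return dx


class GlobalMaxPool(Layer):
    """Adaptive max pool with a 1x1 target: max over all spatial positions."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        B, H, W, C = x.shape
        flat = x.reshape(B, H * W, C)
        idx = np.argmax(flat, axis=1)
        out = np.take_along_axis(flat, idx[:, None, :], axis=1)[:, 0, :]
        if train:
            self._cache = (x.shape, idx)
        return out  # (B, C)

    def backward(self, dout):
        (B, H, W, C), idx = self._cache
        self._cache = None
        dflat = np.zeros((B, H * W, C), dtype=DTYPE)
        np.put_along_axis(dflat, idx[:, None, :], dout[:, None, :], axis=1)
        return dflat.reshape(B, H, W, C)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(
            he_uniform(rng, (out_features, in_features), in_features)
        )
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE))
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        dx = dout @ self.weight.value
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean multiclass cross-entropy over the batch.

    Returns (loss, dlogits); labels are integer class indices.
    """
    B = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(B), labels] + eps))
    d = p
    d[np.arange(B), labels] -= 1.0
    return float(loss), (d / B).astype(DTYPE)


def sigmoid_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean element-wise sigmoid cross-entropy on raw scores.

    Targets are one-hot (or soft) reals in [0, 1]; the mean is taken over
    every element, matching the usual logits-based binary loss.
    """
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    # stable log(1 + exp(-|z|)) formulation
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    sig = 1.0 / (1.0 + np.exp(-z))
    return float(loss.mean()), ((sig - t) / n).astype(DTYPE)


class Adam:
    """Adaptive-moment optimizer (bias-corrected first/second moments)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
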