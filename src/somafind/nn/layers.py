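"""Layers with explicit forward/backward passes (numpy, float32).

Convolution is computed by contracting a sliding-window view of the padded
input against the kernel (an im2col-style GEMM); its input gradient is
accumulated per kernel offset, which keeps memory bounded for large kernels.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv3D",
    "BatchNorm",
    "ReLU",
    "AvgPool2x2x2",
    "GlobalAvgPool",
    "Dense",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _triple(v) -> tuple[int, int, int]:
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v, v)


class Conv3D(Layer):
    """3D convolution, 'same' zero padding, optional stride, no bias (BN follows)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int | tuple[int, int, int],
        stride: int | tuple[int, int, int] = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.pad = tuple(k // 2 for k in self.kernel)
        rng = rng or np.random.default_rng()
        fan_in = in_channels * int(np.prod(self.kernel))
        scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        self.W = Param(rng.normal(0.0, scale, (out_channels, in_channels) + self.kernel))

    def params(self) -> list[Param]:
        return [self.W]

    def _out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple(
            (d + 2 * p - k) // s + 1
            for d, p, k, s in zip(spatial, self.pad, self.kernel, self.stride)
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p1, p2, p3 = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p1, p1), (p2, p2), (p3, p3)))
        self._xp = xp
        self._in_spatial = x.shape[2:]
        s1, s2, s3 = self.stride
        v = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))[:, :, ::s1, ::s2, ::s3]
        return np.einsum(
            "ncxyzuvw,ocuvw->noxyz", v, self.W.value, optimize=True
        ).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s1, s2, s3 = self.stride
        n, cout = grad.shape[:2]
        o1, o2, o3 = grad.shape[2:]
        cin = self.W.value.shape[1]
        k1, k2, k3 = self.kernel
        v = sliding_window_view(self._xp, self.kernel, axis=(2, 3, 4))[:, :, ::s1, ::s2, ::s3]
        self.W.grad += np.einsum("noxyz,ncxyzuvw->ocuvw", grad, v, optimize=True)

        # input gradient: one GEMM producing per-offset contributions, then
        # scatter-add each kernel offset into the padded gradient
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 3, 4, 1)).reshape(-1, cout)
        w2 = self.W.value.reshape(cout, -1)
        contrib = (g2 @ w2).reshape(n, o1, o2, o3, cin, k1, k2, k3)
        contrib = np.moveaxis(contrib, 4, 1)  # (n, cin, o1, o2, o3, k1, k2, k3)
        gxp = np.zeros_like(self._xp)
        for a, b, c in product(range(k1), range(k2), range(k3)):
            gxp[
                :,
                :,
                a : a + s1 * o1 : s1,
                b : b + s2 * o2 : s2,
                c : c + s3 * o3 : s3,
            ] += contrib[..., a, b, c]
        p1, p2, p3 = self.pad
        d1, d2, d3 = self._in_spatial
        self._xp = None
        return gxp[:, :, p1 : p1 + d1, p2 : p2 + d2, p3 : p3 + d3]


class BatchNorm(Layer):
    """Per-channel batch normalisation with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        if train:
            self._xhat = xhat
            self._inv = inv
        return (self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)).astype(
            np.float32
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        xhat, inv = self._xhat, self._inv
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gxhat = grad * self.gamma.value.reshape(shape)
        gx = (
            gxhat
            - gxhat.mean(axis=axes).reshape(shape)
            - xhat * (gxhat * xhat).mean(axis=axes).reshape(shape)
        ) * inv.reshape(shape)
        self._xhat = None
        return gx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class AvgPool2x2x2(Layer):
    """2x2x2 average pooling with stride 2 (trailing odd voxels dropped)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d1, d2, d3 = x.shape
        o1, o2, o3 = d1 // 2, d2 // 2, d3 // 2
        self._in_shape = x.shape
        cropped = x[:, :, : 2 * o1, : 2 * o2, : 2 * o3]
        return cropped.reshape(n, c, o1, 2, o2, 2, o3, 2).mean(axis=(3, 5, 7)).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._in_shape, dtype=np.float32)
        o1, o2, o3 = grad.shape[2:]
        expanded = (
            np.repeat(np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3), 2, axis=4) / 8.0
        )
        gx[:, :, : 2 * o1, : 2 * o2, : 2 * o3] = expanded
        return gx


class GlobalAvgPool(Layer):
    """Average over all spatial positions -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4)).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, d1, d2, d3 = self._in_shape
        scale = 1.0 / (d1 * d2 * d3)
        return (grad[:, :, None, None, None] * scale * np.ones(self._in_shape, np.float32))


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.W = Param(rng.normal(0.0, scale, (out_features, in_features)))
        self.b = Param(np.zeros(out_features))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return (x @ self.W.value.T + self.b.value).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        gx = grad @ self.W.value
        self._x = None
        return gx.astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean categorical cross-entropy.

    Returns (loss, probabilities, gradient w.r.t. logits).  ``labels`` are
    integer class indices; ``sample_weight`` optionally reweights examples.
    """
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    picked = np.clip(probs[np.arange(n), labels], 1e-12, None)
    if sample_weight is None:
        sample_weight = np.ones(n)
    weight_sum = sample_weight.sum()
    loss = float(-(sample_weight * np.log(picked)).sum() / weight_sum)
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (sample_weight / weight_sum)[:, None]
    return loss, probs.astype(np.float32), grad.astype(np.float32)
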