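"""Minimal numpy building blocks for convolutional segmentation networks.

Implements exactly what the U-Net segmenter needs — 2-D convolution, ReLU,
2x2 max pooling, 2x2 stride-2 transposed convolution, channel concatenation,
softmax cross-entropy and the Adam optimizer — with hand-written backward
passes.  All arithmetic is float32; tensors are laid out NHWC, and the k x k
convolution is computed as k^2 shifted channel-matmuls (BLAS-bound, no im2col
buffer).

Weights use Glorot (Xavier) uniform initialization.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "UpConv2",
    "Concat",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]

F32 = np.float32


def xavier_uniform(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Conv2D:
    """k x k same-padding convolution (stride 1), zero-padded borders.

    Weights are stored (k, k, cin, cout); the forward pass accumulates one
    (cin, cout) matmul per kernel tap over the correspondingly shifted view
    of the zero-padded input.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        self.W = xavier_uniform(rng, (k, k, cin, cout), cin * k * k, cout * k * k)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        y = np.broadcast_to(self.b, (n, h, w, self.cout)).copy()
        for i in range(k):
            for j in range(k):
                y += xp[:, i : i + h, j : j + w, :] @ self.W[i, j]
        if train:
            self._xp = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        k, p = self.k, self.k // 2
        xp = self._xp
        self.db[...] = dy.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = xp[:, i : i + h, j : j + w, :]
                self.dW[i, j] = np.tensordot(xs, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i : i + h, j : j + w, :] += dy @ self.W[i, j].T
        self._xp = None
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self):
        return []

    @staticmethod
    def _windows(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        return np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, c, 4)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        xr = self._windows(x)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._xshape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._idx = None
        return np.ascontiguousarray(dx).reshape(n, h, w, c)


class UpConv2:
    """2x2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.W = xavier_uniform(rng, (cin, cout, 2, 2), cin * 4, cout * 4)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        t = np.tensordot(x, self.W, axes=([3], [0]))  # (n, h, w, cout, 2, 2)
        y = np.ascontiguousarray(t.transpose(0, 1, 4, 2, 5, 3)).reshape(
            n, 2 * h, 2 * w, self.cout
        )
        y += self.b
        if train:
            self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, co = dy.shape
        h, w = h2 // 2, w2 // 2
        dyt = dy.reshape(n, h, 2, w, 2, co).transpose(0, 1, 3, 5, 2, 4)
        dyt = np.ascontiguousarray(dyt)  # (n, h, w, cout, 2, 2)
        self.db[...] = dy.sum(axis=(0, 1, 2))
        self.dW[...] = np.tensordot(self._x, dyt, axes=([0, 1, 2], [0, 1, 2]))
        dx = np.tensordot(dyt, self.W, axes=([3, 4, 5], [1, 2, 3]))
        self._x = None
        return dx


class Concat:
    """Channel-wise concatenation of the skip tensor and the upsampled tensor."""

    def __init__(self):
        self._split: int | None = None

    def params(self):
        return []

    def forward(self, skip: np.ndarray, up: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._split = skip.shape[-1]
        return np.concatenate([skip, up], axis=-1)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = self._split
        self._split = None
        return dy[..., :s], dy[..., s:]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean pixel-wise cross-entropy and its gradient w.r.t. the logits.

    ``logits``: (n, h, w, n_classes) float; ``targets``: (n, h, w) int.
    """
    p = softmax(logits.astype(np.float64), axis=-1)
    pt = np.take_along_axis(p, targets[..., None], axis=-1)[..., 0]
    loss = float(-np.log(np.maximum(pt, 1e-12)).mean())
    grad = p
    np.put_along_axis(grad, targets[..., None], pt[..., None] - 1.0, axis=-1)
    grad /= targets.size
    return loss, grad.astype(F32)


class Adam:
    """Adam optimizer over a list of (param, grad) array pairs."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
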