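"""Minimal deterministic CNN engine (numpy, manual backprop).

Layers operate on float32 (B, C, H, W) batches. Convolutions use zero
same-padding and are evaluated as a sum over kernel offsets of channel-mixing
matmuls, which keeps everything in BLAS. All initialization is driven by an
explicit numpy Generator, so training runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "Sequential",
    "ResidualBlock",
    "GlobalAvgPool",
    "Linear",
    "Adam",
    "mse_loss",
    "bce_with_logits",
]


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded 2-D convolution with bias (He-scaled init)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # im2col: one large GEMM beats per-offset small ones on CPU
        b, c, h, w = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        col = np.ascontiguousarray(view.transpose(1, 4, 5, 0, 2, 3)).reshape(
            c * k * k, b * h * w
        )
        self._col = col
        self._in_shape = x.shape
        out = self.w.reshape(-1, c * k * k) @ col
        out += self.b[:, None]
        return np.ascontiguousarray(
            out.reshape(-1, b, h, w).transpose(1, 0, 2, 3)
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        k = self.k
        p = k // 2
        co = self.w.shape[0]
        gf = np.ascontiguousarray(grad.transpose(1, 0, 2, 3)).reshape(co, b * h * w)
        self.db[:] = gf.sum(axis=1)
        self.dw[:] = (gf @ self._col.T).reshape(self.w.shape)
        dcol = (self.w.reshape(co, -1).T @ gf).reshape(c, k, k, b, h, w)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcol[:, i, j].transpose(1, 0, 2, 3)
        self._col = None
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def grads(self):
        return [g for lay in self.layers for g in lay.grads()]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad


class ResidualBlock(Layer):
    """x -> relu(x + conv(relu(conv(x)))), 3x3 kernels, constant width."""

    def __init__(self, channels: int, rng: np.random.Generator, k: int = 3):
        self.conv1 = Conv2d(channels, channels, k, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, k, rng)
        self.relu2 = ReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def grads(self):
        return self.conv1.grads() + self.conv2.grads()

    def forward(self, x):
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu2.forward(x + y)

    def backward(self, grad):
        g = self.relu2.backward(grad)
        gy = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return g + gy


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        b, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            self.w = np.zeros((n_out, n_in), dtype=np.float32)
        else:
            self.w = (rng.standard_normal((n_out, n_in)) * np.sqrt(1.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.dw[:] = grad.T @ self._x
        self.db[:] = grad.sum(axis=0)
        return grad @ self.w


class Adam:
    """Adaptive-moment optimizer updating parameter arrays in place."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff.astype(np.float64) ** 2)), (2.0 / diff.size) * diff


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on raw scores with a logistic link."""
    z = logits.astype(np.float64).ravel()
    y = labels.astype(np.float64).ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = ((p - y) / len(z)).astype(np.float32).reshape(logits.shape)
    return loss, grad
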