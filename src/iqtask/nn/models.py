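"""Trainable models: the SRCNN family and ResNet-based observers.

The SRCNN is a plain feed-forward CNN mapping an LR image to an SR estimate
on the same grid: a 9x9 first layer, 5x5 hidden layers of constant width,
and a 5x5 single-channel output layer, with rectifier nonlinearities between
layers and none after the last.

The ResNet-based observer emits one scalar score per image: a 3x3 stem,
``n_blocks`` residual blocks (two 3x3 convolutions each, additive skip),
global average pooling and a linear head. It can be warm-started from a
regularized-Hotelling template via an additive linear branch
``gain * (w_rho . x)`` whose gain is trainable; with the head zero-initialized
the untrained observer then scores images exactly like the RHO.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from iqtask.nn._engine import (
    Adam,
    Conv2d,
    GlobalAvgPool,
    Linear,
    ReLU,
    ResidualBlock,
    Sequential,
)

__all__ = ["SRNetworkSpec", "ObserverNetworkSpec", "SRCNN", "ResNetObserver"]


@dataclass(frozen=True)
class SRNetworkSpec:
    n_layers: int = 3
    first_filter: int = 9
    hidden_filter: int = 5
    hidden_channels: int = 32
    out_channels: int = 1
    loss: Literal["mse", "mse+adversarial"] = "mse"

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("SRCNN needs at least 2 convolutional layers")
        if self.out_channels != 1:
            raise ValueError("single-channel output expected")


@dataclass(frozen=True)
class ObserverNetworkSpec:
    n_blocks: int = 2
    input_size: int = 64
    channels: int = 32
    init: Literal["random", "rho"] = "random"

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be positive")


class _Model:
    net: Sequential

    def params(self):
        return self.net.params()

    def grads(self):
        return self.net.grads()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s


class SRCNN(_Model):
    """Plain feed-forward SR network.

    ``zero_last`` zero-initializes the output layer so that, under residual
    training, optimization starts exactly at the identity mapping; the
    default is the plain He-initialized direct mapping.
    """

    def __init__(self, spec: SRNetworkSpec, rng: np.random.Generator, zero_last: bool = False):
        self.spec = spec
        hc = spec.hidden_channels
        layers: list = [Conv2d(1, hc, spec.first_filter, rng), ReLU()]
        for _ in range(spec.n_layers - 2):
            layers += [Conv2d(hc, hc, spec.hidden_filter, rng), ReLU()]
        last = Conv2d(hc, 1, spec.hidden_filter, rng)
        if zero_last:
            last.w[...] = 0.0
        layers += [last]
        self.net = Sequential(layers)
        # input/output standardization and residual mode fitted by the trainer
        self.norm_mu = 0.0
        self.norm_sd = 1.0
        self.residual = False
        self.trained = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def predict(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Super-resolve a (N, H, W) stack (normalization handled internally)."""
        images = np.asarray(images, dtype=np.float32)
        out = np.empty_like(images)
        sd = np.float32(self.norm_sd)
        mu = np.float32(self.norm_mu)
        for i in range(0, len(images), batch_size):
            x = (images[i : i + batch_size, None] - mu) / sd
            y = self.net.forward(x)[:, 0]
            # in residual mode the network emits the normalized HR-LR
            # correction, so de-normalization adds the input image, not mu
            out[i : i + batch_size] = y * sd + (images[i : i + batch_size] if self.residual else mu)
        return out


class ResNetObserver(_Model):
    def __init__(
        self,
        spec: ObserverNetworkSpec,
        rng: np.random.Generator,
        warm_start: np.ndarray | None = None,
    ):
        self.spec = spec
        ch = spec.channels
        layers: list = [Conv2d(1, ch, 3, rng), ReLU()]
        for _ in range(spec.n_blocks):
            layers.append(ResidualBlock(ch, rng))
        self.net = Sequential(layers)
        self.pool = GlobalAvgPool()
        self.head = Linear(ch, 1, rng, zero_init=warm_start is not None)
        self.template = None
        self.gain = None
        if warm_start is not None:
            w = np.asarray(warm_start, dtype=np.float32).ravel()
            if w.size != spec.input_size**2:
                raise ValueError(
                    f"warm-start template length {w.size} does not match "
                    f"input size {spec.input_size}^2"
                )
            # scale the template branch so initial scores have O(1) spread
            self.template = w
            self.gain = np.ones(1, dtype=np.float32)
        self.norm_mu = 0.0
        self.norm_sd = 1.0
        self.trained = False
        self._dgain = np.zeros(1, dtype=np.float32) if self.gain is not None else None

    def params(self):
        p = self.net.params() + self.head.params()
        if self.gain is not None:
            p.append(self.gain)
        return p

    def grads(self):
        g = self.net.grads() + self.head.grads()
        if self.gain is not None:
            g.append(self._dgain)
        return g

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Scalar score per image; x is (B, 1, H, W)."""
        feats = self.pool.forward(self.net.forward(x))
        score = self.head.forward(feats)[:, 0]
        if self.template is not None:
            self._tdot = x.reshape(len(x), -1) @ self.template
            score = score + self.gain[0] * self._tdot
        return score

    def backward(self, grad: np.ndarray, x_shape) -> None:
        g2 = self.head.backward(grad[:, None])
        self.net.backward(self.pool.backward(g2))
        if self.template is not None:
            self._dgain[0] = float(grad @ self._tdot)

    def score(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        out = np.empty(len(images), dtype=np.float64)
        sd = np.float32(self.norm_sd)
        mu = np.float32(self.norm_mu)
        for i in range(0, len(images), batch_size):
            x = (images[i : i + batch_size, None] - mu) / sd
            out[i : i + batch_size] = self.forward(x)
        return out


def expected_srcnn_parameters(spec: SRNetworkSpec) -> int:
    """Closed-form trainable parameter count of an SRCNN spec."""
    hc = spec.hidden_channels
    total = spec.first_filter**2 * 1 * hc + hc
    for _ in range(spec.n_layers - 2):
        total += spec.hidden_filter**2 * hc * hc + hc
    total += spec.hidden_filter**2 * hc * 1 + 1
    return total
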