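"""Minimal NumPy CNN engine: layers with explicit backprop, Adam, BCE.

All tensors are NCHW float64.  Convolutions use im2col (matrix-multiply)
with "same" zero padding; upsampling is a 2×2 stride-2 transposed
convolution.  The engine is deliberately small — exactly the layer set a
U-Net needs — and fully deterministic under a seeded generator.

Adam maintains exponential moving averages of the gradient and its square
for every parameter::

    m ← β1·m + (1−β1)·g        v ← β2·v + (1−β2)·g²
    m̂ = m/(1−β1^t)             v̂ = v/(1−β2^t)
    θ ← θ − α·m̂/(√v̂ + ε)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class Param:
    """A trainable array with its gradient accumulator."""

    name: str
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k×k convolution with "same" zero padding (k odd), He-initialized."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, name: str = "conv"):
        if kernel % 2 != 1:
            raise ValueError("Conv2d requires an odd kernel for same padding")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, kernel, kernel))
        self.W = Param(f"{name}.W", w)
        self.b = Param(f"{name}.b", np.zeros(out_channels))
        self._cols: Optional[np.ndarray] = None
        self._shape: Optional[Tuple[int, ...]] = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        view = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k**2)
        wmat = self.W.value.reshape(self.cout, -1)
        out = cols @ wmat.T + self.b.value
        if train:
            self._cols, self._shape = cols, x.shape
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.W.grad += (dmat.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.W.value.reshape(self.cout, -1)).reshape(
            n, h, w, c, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ConvTranspose2d(Layer):
    """2×2 stride-2 transposed convolution: doubles H and W."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, name: str = "upconv"):
        self.cin, self.cout = in_channels, out_channels
        fan_in = in_channels * 4
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(in_channels, out_channels, 2, 2))
        self.W = Param(f"{name}.W", w)
        self.b = Param(f"{name}.b", np.zeros(out_channels))
        self._x: Optional[np.ndarray] = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        t = np.einsum("nchw,cfab->nfhawb", x, self.W.value)
        out = t.reshape(n, self.cout, 2 * h, 2 * w) + self.b.value[None, :, None, None]
        if train:
            self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h2, w2 = dout.shape
        h, w = h2 // 2, w2 // 2
        blocks = dout.reshape(n, f, h, 2, w, 2)  # n f h a w b
        self.W.grad += np.einsum("nchw,nfhawb->cfab", self._x, blocks)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dx = np.einsum("nfhawb,cfab->nchw", blocks, self.W.value)
        self._x = None
        return dx


class Upsample2x(Layer):
    """Parameter-free nearest-neighbor 2× upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dout.shape
        return dout.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        cells = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = cells.reshape(n, c, h // 2, w // 2, 4)
        if train:
            am = np.argmax(flat, axis=-1)  # first max wins on ties
            self._onehot = np.eye(4)[am]
            self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d = (dout[..., None] * self._onehot).reshape(n, c, h // 2, w // 2, 2, 2)
        return d.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return dout
        return dout * self._mask


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


EPS_P = 1e-7  # probability clamp inside the cross-entropy


def bce_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binary cross-entropy −[y·ln p + (1−y)·ln(1−p)] over all pixels."""
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"label shape {y.shape} != prediction shape {p.shape}")
    pc = np.clip(p, EPS_P, 1.0 - EPS_P)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


def adam_reference_step(
    theta: np.ndarray,
    grad: np.ndarray,
    state: Tuple[np.ndarray, np.ndarray, int],
    alpha: float = 1e-4,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> Tuple[np.ndarray, Tuple[np.ndarray, np.ndarray, int]]:
    """One Adam update from explicit (m, v, t) state; returns (θ', state').

    This is the definitional recurrence; the training loop's optimizer is
    verified against it.
    """
    m, v, t = state
    theta = np.asarray(theta, dtype=np.float64)
    grad = np.asarray(grad, dtype=np.float64)
    t = t + 1
    m = beta1 * m + (1.0 - beta1) * grad
    v = beta2 * v + (1.0 - beta2) * grad**2
    m_hat = m / (1.0 - beta1**t)
    v_hat = v / (1.0 - beta2**t)
    theta_new = theta - alpha * m_hat / (np.sqrt(v_hat) + eps)
    return theta_new, (m, v, t)


class Adam:
    """Adam over a list of :class:`Param`, matching ``adam_reference_step``."""

    def __init__(self, params: Sequence[Param], alpha: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.alpha, self.beta1, self.beta2, self.eps = alpha, beta1, beta2, eps
        self.t = 0
        self.m: Dict[int, np.ndarray] = {i: np.zeros_like(p.value)
                                         for i, p in enumerate(self.params)}
        self.v: Dict[int, np.ndarray] = {i: np.zeros_like(p.value)
                                         for i, p in enumerate(self.params)}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g**2
            m_hat = self.m[i] / b1t
            v_hat = self.v[i] / b2t
            p.value -= self.alpha * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)
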