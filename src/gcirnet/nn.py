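"""Minimal NumPy neural-network layers with explicit backpropagation.

Layers operate on channels-last arrays (N, H, W, C) in float64 and cache
what their backward pass needs on the instance, so a layer serves one
forward/backward pair at a time (single-threaded training loop).  Only
the pieces the connectivity-imaging network needs are provided: 3x3
same-padding convolution (stride 1), 2x2 average pooling, 2x2
nearest-neighbor upsampling, dense layers, SELU and sigmoid activations,
and an Adam optimizer.  Initialization is Glorot-uniform under a caller
seeded generator, which makes model construction bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Conv2D",
    "AvgPool2x2",
    "Upsample2x2",
    "Flatten",
    "Reshape",
    "SELU",
    "Sigmoid",
    "Sequential",
    "Adam",
    "softmax",
]

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base layer: parameter-free identity."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ dout
        self.grads[1] += dout.sum(axis=0)
        return dout @ self.W.T


class Conv2D(Layer):
    """3x3 convolution, stride 1, same (zero) padding, channels-last.

    Implemented as nine shifted (N*H*W, Cin) @ (Cin, Cout) products, one
    per kernel tap, which keeps memory linear in the input size.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3) -> None:
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = k
        fan_in, fan_out = k * k * c_in, k * k * c_out
        self.W = _glorot(rng, (k, k, c_in, c_out), fan_in, fan_out)
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp_shape = xp.shape
        self._xp = xp
        out = np.zeros((n, h, w, self.W.shape[-1]))
        for i in range(self.k):
            for j in range(self.k):
                out += xp[:, i : i + h, j : j + w, :] @ self.W[i, j]
        return out + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, _ = dout.shape
        p = self.k // 2
        dxp = np.zeros(self._xp_shape)
        flat_dout = dout.reshape(-1, dout.shape[-1])
        for i in range(self.k):
            for j in range(self.k):
                patch = self._xp[:, i : i + h, j : j + w, :].reshape(-1, self.W.shape[2])
                self.grads[0][i, j] += patch.T @ flat_dout
                dxp[:, i : i + h, j : j + w, :] += dout @ self.W[i, j].T
        self.grads[1] += flat_dout.sum(axis=0)
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class AvgPool2x2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        self._in_shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        up = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2)
        return up / 4.0


class Upsample2x2(Layer):
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class SELU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * np.expm1(x))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        grad = _SELU_SCALE * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(x))
        return dout * grad


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)


class Sequential:
    """Ordered stack of layers with chained forward/backward."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
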