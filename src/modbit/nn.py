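"""Minimal numpy neural-network primitives: valid 3x3 convolutions, 2x2 max
pooling, dense layers, softmax cross-entropy and Adam.

Layers cache their forward inputs for the backward pass; each layer owns a
list of (value, gradient) parameter pairs.  Weight initialization is
Glorot-uniform (fan-scaled), seeded through a numpy Generator so that a
rebuild with the same seed reproduces the initial weights bit-for-bit.
All tensors are float32 in NHWC layout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "MaxPool2D", "Dense", "Adam",
           "softmax", "softmax_cross_entropy", "ACTIVATIONS"]


def _relu(z):
    return np.maximum(z, 0.0)


def _relu_grad(z, a):
    return (z > 0).astype(z.dtype)


def _tanh(z):
    return np.tanh(z)


def _tanh_grad(z, a):
    return 1.0 - a * a


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _sigmoid_grad(z, a):
    return a * (1.0 - a)


def _linear(z):
    return z


def _linear_grad(z, a):
    return np.ones_like(z)


ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "tanh": (_tanh, _tanh_grad),
    "sigmoid": (_sigmoid, _sigmoid_grad),
    "linear": (_linear, _linear_grad),
}


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _glorot_uniform(shape, fan_in, fan_out, rng) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D:
    """Valid (unpadded) convolution with bias and a fused activation."""

    def __init__(self, c_in: int, c_out: int, kernel: int, activation: str,
                 rng: np.random.Generator):
        k = kernel
        fan_in, fan_out = k * k * c_in, k * k * c_out
        self.W = Param(_glorot_uniform((k * k * c_in, c_out), fan_in, fan_out, rng))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self.kernel = k
        self.c_in, self.c_out = c_in, c_out
        self.act, self.act_grad = ACTIVATIONS[activation]
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        k = self.kernel
        oh, ow = H - k + 1, W - k + 1
        cols = np.empty((B, oh, ow, k, k, C), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i, j, :] = x[:, i:i + oh, j:j + ow, :]
        return cols.reshape(B, oh, ow, k * k * C)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = self._im2col(x)
        z = cols @ self.W.value + self.b.value
        a = self.act(z)
        self._cache = (x.shape, cols, z, a)
        return a

    def backward(self, da: np.ndarray) -> np.ndarray:
        (B, H, W, C), cols, z, a = self._cache
        k = self.kernel
        oh, ow = H - k + 1, W - k + 1
        dz = da * self.act_grad(z, a)
        K = k * k * C
        self.W.grad = cols.reshape(-1, K).T @ dz.reshape(-1, self.c_out)
        self.b.grad = dz.sum(axis=(0, 1, 2))
        dcols = (dz @ self.W.value.T).reshape(B, oh, ow, k, k, C)
        dx = np.zeros((B, H, W, C), dtype=da.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        return dx


class MaxPool2D:
    """Non-overlapping 2x2 max pooling; trailing odd rows/columns dropped.

    Backward routes the gradient to the first maximal element of each block.
    """

    def __init__(self, size: int = 2):
        self.size = size
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.size
        B, H, W, C = x.shape
        h2, w2 = H // s, W // s
        blocks = (x[:, : h2 * s, : w2 * s, :]
                  .reshape(B, h2, s, w2, s, C)
                  .transpose(0, 1, 3, 5, 2, 4)
                  .reshape(B, h2, w2, C, s * s))
        idx = blocks.argmax(axis=4)
        out = np.take_along_axis(blocks, idx[..., None], axis=4)[..., 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self.size
        (B, H, W, C), idx = self._cache
        h2, w2 = H // s, W // s
        dblocks = np.zeros((B, h2, w2, C, s * s), dtype=dout.dtype)
        np.put_along_axis(dblocks, idx[..., None], dout[..., None], axis=4)
        dx = np.zeros((B, H, W, C), dtype=dout.dtype)
        dx[:, : h2 * s, : w2 * s, :] = (dblocks
                                        .reshape(B, h2, w2, C, s, s)
                                        .transpose(0, 1, 4, 2, 5, 3)
                                        .reshape(B, h2 * s, w2 * s, C))
        return dx


class Dense:
    """Fully connected layer; exposes its pre-activation for probing."""

    def __init__(self, n_in: int, n_out: int, activation: str,
                 rng: np.random.Generator):
        self.W = Param(_glorot_uniform((n_in, n_out), n_in, n_out, rng))
        self.b = Param(np.zeros(n_out, dtype=np.float32))
        self.act, self.act_grad = ACTIVATIONS[activation]
        self.n_in, self.n_out = n_in, n_out
        self._cache = None
        self.preact: np.ndarray | None = None  # last forward's z

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.W.value + self.b.value
        a = self.act(z)
        self._cache = (x, z, a)
        self.preact = z
        return a

    def backward(self, da: np.ndarray) -> np.ndarray:
        x, z, a = self._cache
        dz = da * self.act_grad(z, a)
        self.W.grad = x.T @ dz
        self.b.grad = dz.sum(axis=0)
        return dz @ self.W.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray,
                          labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy on integer labels; returns (loss, dlogits, probs)."""
    p = softmax(logits)
    n = len(labels)
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits.astype(np.float32), p


class Adam:
    """Adam optimizer with the standard defaults (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Param], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.value.dtype)
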