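"""Minimal NumPy neural-network primitives (manual gradients).

No deep-learning framework is assumed in the runtime environment, so the
VAE and the CNN are built from these hand-differentiated building blocks.
All stochastic pieces take an explicit Generator; everything is pure NumPy,
hence bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x: (B, L, Cin); w: (k, Cin, Cout); 'valid' convolution -> (B, L-k+1, Cout)."""
    k = w.shape[0]
    T = x.shape[1] - k + 1
    out = np.zeros((x.shape[0], T, w.shape[2]))
    for j in range(k):
        out += x[:, j:j + T, :] @ w[j]
    return out + b


def conv1d_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    """Returns (dx, dw, db) for conv1d_forward."""
    k = w.shape[0]
    T = dout.shape[1]
    dx = np.zeros_like(x)
    dw = np.zeros_like(w)
    for j in range(k):
        dx[:, j:j + T, :] += dout @ w[j].T
        dw[j] = np.einsum("btc,bto->co", x[:, j:j + T, :], dout)
    db = dout.sum(axis=(0, 1))
    return dx, dw, db


def maxpool_forward(x: np.ndarray, size: int = 2):
    """Non-overlapping max pool along axis 1 (floor division of length)."""
    B, L, C = x.shape
    T = L // size
    view = x[:, : T * size, :].reshape(B, T, size, C)
    arg = view.argmax(axis=2)
    out = view.max(axis=2)
    return out, (arg, x.shape, size)


def maxpool_backward(dout: np.ndarray, cache) -> np.ndarray:
    arg, shape, size = cache
    B, L, C = shape
    T = dout.shape[1]
    dview = np.zeros((B, T, size, C))
    b_idx, t_idx, c_idx = np.ogrid[:B, :T, :C]
    dview[b_idx, t_idx, arg, c_idx] = dout
    dx = np.zeros(shape)
    dx[:, : T * size, :] = dview.reshape(B, T * size, C)
    return dx
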