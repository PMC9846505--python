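"""Numpy building blocks of the integration network.

Each layer is a small object with ``forward(x, train)`` and
``backward(grad_out)``; ``backward`` accumulates parameter gradients in
``.grads`` (aligned with ``.params``) and returns the gradient with respect
to the layer input. Training uses these directly — there is no autograd.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["glorot_uniform", "gelu", "gelu_grad", "Affine", "BatchNorm", "SelfAttention", "softmax"]


def glorot_uniform(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact Gaussian Error Linear Unit, x * Phi(x) (no tanh approximation)."""
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    """d/dx [x Phi(x)] = Phi(x) + x phi(x)."""
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
    return cdf + x * phi


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Affine:
    """Fully-connected layer y = x W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = glorot_uniform(rng, n_in, n_out)
        self.b = np.zeros(n_out)
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ g
        self.grads[1] += g.sum(axis=0)
        return g @ self.W.T


class BatchNorm:
    """Batch normalization with learned scale/shift and running statistics.

    Train mode normalizes by batch statistics (population variance) and
    updates exponential running averages; inference mode uses the running
    statistics, making the forward pass a fixed per-feature affine map.
    """

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv_sd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_sd
            self._cache = (xhat, inv_sd)
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_sd = self._cache
        n = g.shape[0]
        self.grads[0] += (g * xhat).sum(axis=0)
        self.grads[1] += g.sum(axis=0)
        gx = g * self.gamma
        # standard batch-norm backward through batch mean and variance
        return inv_sd / n * (n * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0))


class SelfAttention:
    """Sample-wise scaled dot-product self-attention.

    Queries, keys and values are linear projections of the same N x d_k
    input; output row i is the softmax((q_i . k_j)/sqrt(d_k))-weighted sum
    of value rows, so every sample's representation mixes information from
    its co-batched samples.
    """

    def __init__(self, d_k: int, rng: np.random.Generator):
        self.Wq = glorot_uniform(rng, d_k, d_k)
        self.Wk = glorot_uniform(rng, d_k, d_k)
        self.Wv = glorot_uniform(rng, d_k, d_k)
        self.d_k = d_k
        self.grads = [np.zeros_like(self.Wq), np.zeros_like(self.Wk), np.zeros_like(self.Wv)]
        self._cache = None
        self.last_weights: np.ndarray | None = None

    @property
    def params(self):
        return [self.Wq, self.Wk, self.Wv]

    def forward(self, y: np.ndarray, train: bool = True) -> np.ndarray:
        q = y @ self.Wq
        k = y @ self.Wk
        v = y @ self.Wv
        w = softmax(q @ k.T / np.sqrt(self.d_k), axis=1)
        if not np.all(np.isfinite(w)):
            raise FloatingPointError("non-finite attention weights")
        z = w @ v
        self.last_weights = w
        if train:
            self._cache = (y, q, k, v, w)
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        y, q, k, v, w = self._cache
        dv = w.T @ g
        dw = g @ v.T
        ds = w * (dw - (dw * w).sum(axis=1, keepdims=True))  # softmax jacobian
        scale = 1.0 / np.sqrt(self.d_k)
        dq = ds @ k * scale
        dk = ds.T @ q * scale
        self.grads[0] += y.T @ dq
        self.grads[1] += y.T @ dk
        self.grads[2] += y.T @ dv
        return dq @ self.Wq.T + dk @ self.Wk.T + dv @ self.Wv.T


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
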