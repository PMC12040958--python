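"""Minimal dense neural-network primitives with hand-derived gradients.

Everything here is plain NumPy: a fully connected layer caching its input for
the backward pass, the ELU activation, a numerically safe sigmoid, and an Adam
optimizer.  Gradients are exact (verified by finite differences in the test
suite), and all computation is deterministic for a fixed seed.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Tuple

import numpy as np

__all__ = ["Dense", "elu", "elu_backward", "sigmoid", "Adam"]


class Dense:
    """Affine layer y = x W + b with cached input and accumulated gradients."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style scaling, appropriate for the ELU nonlinearity downstream
        self.W = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients; return gradient w.r.t. the input."""
        self.gW += self._x.T @ grad_out
        self.gb += grad_out.sum(axis=0)
        return grad_out @ self.W.T

    def zero_grad(self) -> None:
        self.gW[:] = 0.0
        self.gb[:] = 0.0

    @property
    def params_and_grads(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        return [(self.W, self.gW), (self.b, self.gb)]


def elu(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Exponential Linear Unit: x for x > 0, alpha (e^x - 1) otherwise."""
    return np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


def elu_backward(grad_out: np.ndarray, x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    return grad_out * np.where(x > 0, 1.0, alpha * np.exp(np.minimum(x, 0.0)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(np.asarray(x, dtype=float))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimizer over a fixed list of (parameter, gradient) array pairs."""

    def __init__(
        self,
        params_and_grads: Iterable[Tuple[np.ndarray, np.ndarray]],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.pairs = list(params_and_grads)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
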