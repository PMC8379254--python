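"""Minimal NumPy neural-network primitives with hand-derived gradients.

Both model architectures in this package are small enough that explicit
reverse-mode gradients over dense layers are simpler and more transparent
than a full autodiff framework. Layers cache their forward activations;
``backward`` consumes the upstream gradient and accumulates parameter
gradients. Parameter updates use Adam.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLP", "Adam", "relu", "softmax", "one_hot"]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


class Dense:
    """Fully connected layer ``y = x @ W + b`` with cached input."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He initialization, suits ReLU hidden layers
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        # collapse any leading batch dimensions
        x2 = x.reshape(-1, x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.dW += x2.T @ g2
        self.db += g2.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0


class MLP:
    """Stack of Dense layers with ReLU between them (linear output)."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.layers = [Dense(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self._pre: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pre = []
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if i < len(self.layers) - 1:
                self._pre.append(x)
                x = relu(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                grad = grad * (self._pre[i] > 0)
            grad = self.layers[i].backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
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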