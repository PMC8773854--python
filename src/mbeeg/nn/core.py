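"""Minimal neural-network engine: parameters, layer protocol, losses, optimizers.

The package trains its convolutional models with this small, explicit
numpy engine (forward + hand-derived backward per layer, Adam/SGD
updates).  It is deliberately limited to the layer vocabulary the model
family needs; correctness is pinned down by finite-difference gradient
checks in the test-suite rather than by an autodiff framework.

Conventions
-----------
* Batches are leading: epoched input is ``(N, E, T)``; inside a branch
  tensors are channels-last ``(N, T, C)``.
* ``forward(x, training=..., rng=...)`` caches whatever ``backward(dy)``
  needs; ``backward`` accumulates parameter gradients and returns the
  input gradient (entry layers may return ``None`` since epoched data
  needs no gradient).
* All randomness (dropout, initialization) flows through
  ``numpy.random.Generator`` objects supplied by the caller.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "SGD",
    "glorot_uniform",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad", "constraint")

    def __init__(self, name: str, value: np.ndarray, constraint=None):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)
        self.constraint = constraint

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name!r}, shape={self.value.shape})"


class Layer:
    """Base layer: stateless unless it declares params or running state."""

    def params(self) -> list[Param]:
        return []

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        return {}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for key, val in self.state().items():
            val[...] = state[key]

    def forward(self, x, training: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Sequential(Layer):
    """Chain of layers; ``backward`` runs in reverse."""

    def __init__(self, layers: list[Layer], name: str = "seq"):
        self.layers = layers
        self.name = name

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for key, val in layer.state().items():
                out[f"{i}:{key}"] = val
        return out

    def load_state(self, state):
        for i, layer in enumerate(self.layers):
            sub = {k.split(":", 1)[1]: v for k, v in state.items() if k.startswith(f"{i}:")}
            if sub:
                layer.load_state(sub)

    def forward(self, x, training=False, rng=None, **first_layer_kwargs):
        for i, layer in enumerate(self.layers):
            kwargs = first_layer_kwargs if i == 0 else {}
            x = layer.forward(x, training=training, rng=rng, **kwargs)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax probabilities (numerically shifted)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, log_base: float = np.e
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. logits.

    ``log_base`` only rescales the reported loss (and gradient) by a
    constant factor; the default natural log is standard practice.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    scale = 1.0 / np.log(log_base)
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean() * scale)
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= scale / n
    return loss, dlogits


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype=np.float32):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Adam:
    """Adam with bias correction (Kingma & Ba defaults except ``lr``)."""

    def __init__(self, params: list[Param], lr: float = 9e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if p.constraint is not None:
                p.value[...] = p.constraint(p.value)


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, params: list[Param], lr: float = 9e-4):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            p.value -= self.lr * p.grad
            if p.constraint is not None:
                p.value[...] = p.constraint(p.value)
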