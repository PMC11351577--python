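"""Small neural-net primitives shared by the backbone and dense head."""

from __future__ import annotations

import numpy as np

__all__ = ["relu", "softmax", "cross_entropy", "he_init", "Adam"]


def relu(x):
    """Rectified linear unit, max(0, x), elementwise."""
    return np.maximum(0.0, x)


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, label: int) -> float:
    """Negative log-likelihood of the true class, clipped away from log 0."""
    p = float(np.clip(probs[..., label], 1e-12, 1.0))
    return -np.log(p)


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He-style normal initialization scaled by sqrt(2 / fan_in)."""
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if self.lr == 0.0:
            return  # explicit no-op contract
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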