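"""Fully connected classifier head mapping the 5 measured values to 3 classes.

Architecture: dense layers of 100, 50 and 20 ReLU units followed by a
3-unit softmax output — one probability per class (normal, benign,
malignant). Training is softmax cross-entropy; the backward pass also
returns the gradient with respect to the 5-dimensional input so the quantum
layer upstream can be chained through the parameter-shift Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import cross_entropy, he_init, relu, softmax
from .errors import ValidationError
from .seeding import stage_rng

__all__ = ["DenseHead", "head_forward", "head_loss_and_grads"]

DEFAULT_SIZES = (100, 50, 20, 3)


@dataclass
class DenseHead:
    """Weights and biases of the fully connected stack."""

    input_dim: int = 5
    layer_sizes: tuple[int, ...] = DEFAULT_SIZES
    seed: int = 0
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        if not self.weights:
            rng = stage_rng(self.seed, "dense-head-init")
            fan_in = self.input_dim
            for width in self.layer_sizes:
                self.weights.append(he_init(rng, (width, fan_in), fan_in))
                self.biases.append(np.zeros(width))
                fan_in = width

    @property
    def n_classes(self) -> int:
        return self.layer_sizes[-1]

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DenseHead":
        return cls(
            input_dim=d["input_dim"],
            layer_sizes=tuple(d["layer_sizes"]),
            weights=[np.asarray(w, float) for w in d["weights"]],
            biases=[np.asarray(b, float) for b in d["biases"]],
        )


def _forward_pass(head: DenseHead, x: np.ndarray):
    """Return (probs, per-layer pre-activations, per-layer inputs)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != head.input_dim:
        raise ValidationError(
            f"head expects input of length {head.input_dim}, got {x.size}"
        )
    inputs, preacts = [], []
    a = x
    n_layers = len(head.weights)
    for i, (w, b) in enumerate(zip(head.weights, head.biases)):
        inputs.append(a)
        z = w @ a + b
        preacts.append(z)
        a = z if i == n_layers - 1 else relu(z)
    return softmax(a), preacts, inputs


def head_forward(head: DenseHead, x: np.ndarray) -> np.ndarray:
    """Class probabilities (nonnegative, summing to 1) for one input."""
    probs, _, _ = _forward_pass(head, x)
    return probs


def head_loss_and_grads(head: DenseHead, x: np.ndarray, label: int):
    """Cross-entropy loss, parameter gradients, and input gradient.

    Returns ``(loss, grads_w, grads_b, grad_x)`` where ``grad_x`` has the
    head's input length so an upstream layer can apply the chain rule.
    """
    if label not in range(head.n_classes):
        raise ValidationError(f"label must be in [0, {head.n_classes}), got {label}")
    probs, preacts, inputs = _forward_pass(head, x)
    loss = cross_entropy(probs, label)

    delta = probs.copy()
    delta[label] -= 1.0  # d loss / d logits
    grads_w = [None] * len(head.weights)
    grads_b = [None] * len(head.biases)
    for i in range(len(head.weights) - 1, -1, -1):
        grads_w[i] = np.outer(delta, inputs[i])
        grads_b[i] = delta.copy()
        if i > 0:
            delta = (head.weights[i].T @ delta) * (preacts[i - 1] > 0)
    grad_x = head.weights[0].T @ grads_b[0]
    return loss, grads_w, grads_b, grad_x
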