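"""The trainable variational quantum layer: 5 features in, 5 expectations out.

Assembly, per forward pass: a Hadamard wall on every qubit, RY angle
embedding of the (min-max scaled) quantum features — one feature per qubit —
then ``n_var_layers`` variational blocks of per-qubit RY rotations followed
by a linear CNOT entangling chain (0->1, 1->2, ..., 3->4), and finally a
Pauli-Z expectation on each qubit. Outputs are deterministic reals in
[-1, 1].

Input features are mapped onto [0, pi] by a per-feature min-max scaler fit
on training data (a constant feature maps to pi/2; out-of-range inference
values are clamped). On that range the H -> RY(phi) -> <Z> composition is
the injective curve -sin(phi), so the embedding loses no ordering
information.

Gradients with respect to the variational parameters use the parameter-shift
rule and agree with finite differences to ~1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .qsim import Circuit, _apply_cnot, _apply_single

__all__ = ["AngleScaler", "CircuitSpec", "fit_scaler", "forward", "gradients",
           "as_circuit"]


@dataclass
class AngleScaler:
    """Per-feature linear map from the training range onto [0, pi]."""

    mins: np.ndarray
    maxes: np.ndarray

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxes = np.asarray(self.maxes, dtype=float)
        if self.mins.shape != self.maxes.shape:
            raise ValidationError("scaler mins/maxes shape mismatch")

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        span = self.maxes - self.mins
        degenerate = span <= 0
        span_safe = np.where(degenerate, 1.0, span)
        scaled = (values - self.mins) / span_safe * np.pi
        scaled = np.where(degenerate, np.pi / 2.0, scaled)
        return np.clip(scaled, 0.0, np.pi)

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxes": self.maxes.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AngleScaler":
        return cls(np.asarray(d["mins"]), np.asarray(d["maxes"]))


def fit_scaler(train_features: np.ndarray) -> AngleScaler:
    """Record per-feature min/max over an (n >= 2, k) training matrix."""
    train_features = np.asarray(train_features, dtype=float)
    if train_features.ndim != 2 or train_features.shape[0] < 2:
        raise ValidationError("scaler fitting needs at least 2 training rows")
    return AngleScaler(train_features.min(axis=0), train_features.max(axis=0))


@dataclass
class CircuitSpec:
    """Layer configuration plus its trainable parameter vector.

    ``params`` has length ``n_qubits * n_var_layers`` (row-major: layer, then
    qubit). ``entangler`` may be ``"chain_cnot"`` or ``"none"``.
    """

    n_qubits: int = 5
    n_var_layers: int = 2
    embedding: str = "angle_ry"
    entangler: str = "chain_cnot"
    params: np.ndarray | None = None
    scaler: AngleScaler | None = None

    def __post_init__(self):
        if self.embedding != "angle_ry":
            raise ValidationError(f"unknown embedding {self.embedding!r}")
        if self.entangler not in ("chain_cnot", "none"):
            raise ValidationError(f"unknown entangler {self.entangler!r}")
        n_params = self.n_qubits * self.n_var_layers
        if self.params is None:
            self.params = np.zeros(n_params)
        self.params = np.asarray(self.params, dtype=float)
        if self.params.shape != (n_params,):
            raise ValidationError(
                f"params must have length n_qubits*n_var_layers = {n_params}"
            )

    @property
    def n_params(self) -> int:
        return self.params.size

    def to_dict(self) -> dict:
        return {
            "n_qubits": self.n_qubits, "n_var_layers": self.n_var_layers,
            "embedding": self.embedding, "entangler": self.entangler,
            "params": self.params.tolist(),
            "scaler": self.scaler.to_dict() if self.scaler else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitSpec":
        scaler = AngleScaler.from_dict(d["scaler"]) if d.get("scaler") else None
        return cls(n_qubits=d["n_qubits"], n_var_layers=d["n_var_layers"],
                   embedding=d["embedding"], entangler=d["entangler"],
                   params=np.asarray(d["params"]), scaler=scaler)


def _scaled_angles(spec: CircuitSpec, features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float).ravel()
    if features.size != spec.n_qubits:
        raise ValidationError(
            f"expected {spec.n_qubits} quantum features, got {features.size}"
        )
    return spec.scaler.transform(features) if spec.scaler else features


_H = np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2.0)


def _ry_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array([[c, -s], [s, c]], dtype=complex)


def _embed_amps(spec: CircuitSpec, angles: np.ndarray) -> np.ndarray:
    """|0..0> through the Hadamard wall and RY angle embedding."""
    n = spec.n_qubits
    amps = np.zeros(2**n, dtype=complex)
    amps[0] = 1.0
    for q in range(n):
        amps = _apply_single(amps, n, _H, q)
    for q in range(n):
        amps = _apply_single(amps, n, _ry_matrix(angles[q]), q)
    return amps


def _var_amps(spec: CircuitSpec, amps: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Variational blocks (per-qubit RY then the CNOT chain) on given amps."""
    n = spec.n_qubits
    for layer in range(spec.n_var_layers):
        for q in range(n):
            theta = params[layer * n + q]
            amps = _apply_single(amps, n, _ry_matrix(theta), q)
        if spec.entangler == "chain_cnot":
            for q in range(n - 1):
                amps = _apply_cnot(amps, n, q, q + 1)
    return amps


def _run_amps(spec: CircuitSpec, angles: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Raw-amplitude circuit execution (hot path; no per-gate revalidation)."""
    return _var_amps(spec, _embed_amps(spec, angles), params)


def _z_expectations(n: int, amps: np.ndarray) -> np.ndarray:
    probs = np.abs(amps) ** 2
    bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    return probs @ (1.0 - 2.0 * bits)


def forward(spec: CircuitSpec, features: np.ndarray,
            params: np.ndarray | None = None) -> np.ndarray:
    """Run the circuit on one feature vector; returns <Z> per qubit."""
    angles = _scaled_angles(spec, features)
    p = spec.params if params is None else np.asarray(params, dtype=float)
    return _z_expectations(spec.n_qubits, _run_amps(spec, angles, p))


def gradients(spec: CircuitSpec, features: np.ndarray) -> np.ndarray:
    """Parameter-shift Jacobian, shape (n_qubits outputs, n_params).

    The post-embedding state is computed once and reused across all
    2 * n_params shifted evaluations.
    """
    angles = _scaled_angles(spec, features)
    base = _embed_amps(spec, angles)
    n_out, n_par = spec.n_qubits, spec.n_params
    jac = np.zeros((n_out, n_par))
    for j in range(n_par):
        plus = spec.params.copy()
        plus[j] += np.pi / 2.0
        minus = spec.params.copy()
        minus[j] -= np.pi / 2.0
        f_plus = _z_expectations(n_out, _var_amps(spec, base, plus))
        f_minus = _z_expectations(n_out, _var_amps(spec, base, minus))
        jac[:, j] = (f_plus - f_minus) / 2.0
    return jac


def as_circuit(spec: CircuitSpec, features: np.ndarray) -> Circuit:
    """Serializable gate-list form of the circuit for one input.

    Embedding angles are frozen as fixed params; variational angles are
    bound to parameter slots 0..n_params-1.
    """
    angles = _scaled_angles(spec, features)
    circ = Circuit(n_qubits=spec.n_qubits)
    for q in range(spec.n_qubits):
        circ.add("h", qubit=q)
    for q in range(spec.n_qubits):
        circ.add("ry", qubit=q, param=float(angles[q]))
    for layer in range(spec.n_var_layers):
        for q in range(spec.n_qubits):
            circ.add("ry", qubit=q, param_slot=layer * spec.n_qubits + q)
        if spec.entangler == "chain_cnot":
            for q in range(spec.n_qubits - 1):
                circ.add("cnot", control=q, target=q + 1)
    return circ
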