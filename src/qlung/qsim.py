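"""A dense statevector simulator for small qubit registers.

The register state is the complex amplitude vector over all 2^n
computational basis states, with qubit 0 the least-significant bit of the
basis index (little-endian). Gates are 2x2 unitaries applied to one
addressed qubit (plus CNOT for entanglement); measurement is the
deterministic Pauli-Z expectation sum_i |a_i|^2 (+1 if the qubit bit is 0,
-1 if it is 1), with an optional shot-sampling mode for demonstration.

Gradients of rotation-gate parameters use the parameter-shift rule,
(f(theta + pi/2) - f(theta - pi/2)) / 2, which is exact for RY/RZ
generators — the property that makes the variational circuit trainable by
ordinary gradient descent.

The simulator is dense and capped at 12 qubits; the classifier uses 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "MAX_QUBITS",
    "StateVector",
    "Gate",
    "init_state",
    "hadamard",
    "phase_gate",
    "rotation_y",
    "rotation_z",
    "cnot",
    "apply_gate",
    "expectation_z",
    "sample_z",
    "parameter_shift_gradient",
    "Circuit",
]

MAX_QUBITS = 12
_NORM_TOL = 1e-10
_UNITARY_TOL = 1e-12


@dataclass
class StateVector:
    """Complex amplitudes over the 2^n computational basis states."""

    amplitudes: np.ndarray
    n_qubits: int

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        if self.amplitudes.shape != (2**self.n_qubits,):
            raise ValidationError(
                f"amplitude vector must have length 2^{self.n_qubits}"
            )
        norm = float(np.sum(np.abs(self.amplitudes) ** 2))
        if abs(norm - 1.0) > 1e-6:
            raise ValidationError(f"state norm^2 = {norm}, expected 1")

    @property
    def norm(self) -> float:
        return float(np.sqrt(np.sum(np.abs(self.amplitudes) ** 2)))

    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2


@dataclass
class Gate:
    """A named single-qubit unitary, or the CNOT marker.

    Single-qubit gates carry a 2x2 complex matrix (checked unitary within
    1e-12 at construction); the CNOT carries no matrix and is applied by
    basis-state permutation.
    """

    name: str
    matrix: np.ndarray | None = None
    parameter: float | None = None

    def __post_init__(self):
        if self.matrix is not None:
            m = np.asarray(self.matrix, dtype=complex)
            if m.shape != (2, 2):
                raise ValidationError("single-qubit gate matrix must be 2x2")
            if not np.allclose(m.conj().T @ m, np.eye(2), atol=_UNITARY_TOL):
                raise ValidationError(f"gate {self.name!r} matrix is not unitary")
            self.matrix = m

    @property
    def is_cnot(self) -> bool:
        return self.matrix is None


def init_state(n_qubits: int) -> StateVector:
    """All qubits initialized to |0>: amplitude 1 on |00...0>."""
    if not 1 <= n_qubits <= MAX_QUBITS:
        raise ValidationError(f"n_qubits must be in [1, {MAX_QUBITS}], got {n_qubits}")
    amps = np.zeros(2**n_qubits, dtype=complex)
    amps[0] = 1.0
    return StateVector(amps, n_qubits)


def hadamard() -> Gate:
    """H = (1/sqrt 2) [[1, 1], [1, -1]]: |0> -> (|0>+|1>)/sqrt 2."""
    return Gate("h", np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2.0))


def phase_gate() -> Gate:
    """S (a.k.a. P) = [[1, 0], [0, i]]: multiplies the |1> amplitude by i."""
    return Gate("s", np.array([[1, 0], [0, 1j]], dtype=complex))


def rotation_y(theta: float) -> Gate:
    """RY(theta) = exp(-i theta Y / 2); RY(0) is the identity."""
    if not np.isfinite(theta):
        raise ValidationError("rotation angle must be finite")
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return Gate("ry", np.array([[c, -s], [s, c]], dtype=complex), parameter=theta)


def rotation_z(theta: float) -> Gate:
    """RZ(theta) = diag(e^{-i theta/2}, e^{i theta/2})."""
    if not np.isfinite(theta):
        raise ValidationError("rotation angle must be finite")
    e = np.exp(-0.5j * theta)
    return Gate("rz", np.array([[e, 0], [0, e.conjugate()]], dtype=complex),
                parameter=theta)


def cnot() -> Gate:
    """Controlled-NOT marker; applied with explicit control/target indices."""
    return Gate("cnot", matrix=None)


def _apply_single(amps: np.ndarray, n: int, m: np.ndarray, qubit: int) -> np.ndarray:
    # Little-endian: reshape so the addressed qubit is the middle axis.
    view = amps.reshape(2 ** (n - 1 - qubit), 2, 2**qubit)
    a0, a1 = view[:, 0, :], view[:, 1, :]
    out = np.empty_like(view)
    out[:, 0, :] = m[0, 0] * a0 + m[0, 1] * a1
    out[:, 1, :] = m[1, 0] * a0 + m[1, 1] * a1
    return out.reshape(amps.shape)


def _apply_cnot(amps: np.ndarray, n: int, control: int, target: int) -> np.ndarray:
    idx = np.arange(2**n)
    active = (idx >> control) & 1 == 1
    out = amps.copy()
    out[idx[active]] = amps[idx[active] ^ (1 << target)]
    return out


def apply_gate(
    state: StateVector,
    gate: Gate,
    qubit: int | None = None,
    control: int | None = None,
    target: int | None = None,
) -> StateVector:
    """Apply a gate to the addressed qubit(s); returns a new state.

    Single-qubit gates take ``qubit``; CNOT takes ``control`` and ``target``
    (distinct). The update touches only the addressed axes of the state
    tensor, so cost is O(2^n) per gate.
    """
    n = state.n_qubits
    if gate.is_cnot:
        if control is None or target is None:
            raise ValidationError("CNOT requires control and target indices")
        if not (0 <= control < n and 0 <= target < n):
            raise ValidationError(f"qubit index out of range for {n} qubits")
        if control == target:
            raise ValidationError("CNOT control and target must differ")
        amps = _apply_cnot(state.amplitudes, n, control, target)
    else:
        if qubit is None:
            qubit = target
        if qubit is None or not 0 <= qubit < n:
            raise ValidationError(f"qubit index {qubit} out of range for {n} qubits")
        amps = _apply_single(state.amplitudes, n, gate.matrix, qubit)
    return StateVector(amps, n)


def expectation_z(state: StateVector, qubit: int) -> float:
    """Deterministic <Z> on one qubit: +1 weight for bit 0, -1 for bit 1."""
    n = state.n_qubits
    if not 0 <= qubit < n:
        raise ValidationError(f"qubit index {qubit} out of range for {n} qubits")
    probs = state.probabilities()
    bits = (np.arange(2**n) >> qubit) & 1
    return float(np.sum(probs * (1.0 - 2.0 * bits)))


def sample_z(state: StateVector, qubit: int, shots: int,
             rng: np.random.Generator) -> float:
    """Shot-sampled <Z> estimate (demonstration mode, not used in training)."""
    if shots < 1:
        raise ValidationError("shots must be >= 1")
    p_plus = (1.0 + expectation_z(state, qubit)) / 2.0
    ups = rng.binomial(shots, min(max(p_plus, 0.0), 1.0))
    return (2.0 * ups - shots) / shots


def parameter_shift_gradient(
    runner: Callable[[np.ndarray], float], angles: Sequence[float], index: int
) -> float:
    """Exact derivative of a rotation-gate parameter by the shift rule.

    ``runner`` evaluates the scalar observable at a full angle vector; the
    addressed parameter must enter only through RY/RZ gates.
    """
    angles = np.asarray(angles, dtype=float)
    if not 0 <= index < angles.size:
        raise ValidationError(f"parameter index {index} out of range")
    plus = angles.copy()
    plus[index] += np.pi / 2.0
    minus = angles.copy()
    minus[index] -= np.pi / 2.0
    return (runner(plus) - runner(minus)) / 2.0


@dataclass
class Circuit:
    """An ordered gate list with named parameter slots, JSON-serializable.

    Each op is a dict: ``{"gate": name, "qubit"/"control"+"target": index,
    "param_slot": int | None, "param": float | None}``. A ``param_slot``
    binds the op's angle to an entry of the parameter vector at run time;
    a fixed ``param`` freezes it.
    """

    n_qubits: int
    ops: list[dict] = field(default_factory=list)

    _FACTORIES = {"h": lambda p: hadamard(), "s": lambda p: phase_gate(),
                  "ry": rotation_y, "rz": rotation_z}

    def add(self, gate: str, qubit: int | None = None, control: int | None = None,
            target: int | None = None, param_slot: int | None = None,
            param: float | None = None) -> "Circuit":
        if gate not in ("h", "s", "ry", "rz", "cnot"):
            raise ValidationError(f"unknown gate {gate!r}")
        self.ops.append({"gate": gate, "qubit": qubit, "control": control,
                         "target": target, "param_slot": param_slot, "param": param})
        return self

    @property
    def n_params(self) -> int:
        slots = [op["param_slot"] for op in self.ops if op["param_slot"] is not None]
        return max(slots) + 1 if slots else 0

    def run(self, params: Sequence[float] | None = None,
            state: StateVector | None = None) -> StateVector:
        params = np.asarray(params if params is not None else [], dtype=float)
        if params.size < self.n_params:
            raise ValidationError(
                f"circuit needs {self.n_params} parameters, got {params.size}"
            )
        st = state if state is not None else init_state(self.n_qubits)
        for op in self.ops:
            name = op["gate"]
            if name == "cnot":
                st = apply_gate(st, cnot(), control=op["control"], target=op["target"])
                continue
            if name in ("ry", "rz"):
                angle = (params[op["param_slot"]] if op["param_slot"] is not None
                         else op["param"])
                gate = self._FACTORIES[name](float(angle))
            else:
                gate = self._FACTORIES[name](None)
            st = apply_gate(st, gate, qubit=op["qubit"])
        return st

    def to_json(self) -> str:
        return json.dumps({"n_qubits": self.n_qubits, "ops": self.ops})

    @classmethod
    def from_json(cls, text: str) -> "Circuit":
        data = json.loads(text)
        return cls(n_qubits=data["n_qubits"], ops=data["ops"])
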