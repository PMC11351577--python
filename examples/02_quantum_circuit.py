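"""Tour of the statevector simulator: superposition, entanglement, gradients.

Shows the building blocks of the classifier's quantum layer: the Hadamard
gate creating an equal superposition, a CNOT creating a Bell pair, and the
parameter-shift rule recovering an exact derivative of a rotation angle.
"""

import numpy as np

from qlung.qsim import (apply_gate, cnot, expectation_z, hadamard, init_state,
                        parameter_shift_gradient, rotation_y)

# |0> -> H -> equal superposition: amplitudes (1/sqrt2, 1/sqrt2)
state = apply_gate(init_state(1), hadamard(), qubit=0)
print("H|0> amplitudes:", np.round(state.amplitudes.real, 8))
print("<Z> after H (0 = fully undecided):", round(expectation_z(state, 0), 12))

# Bell pair: H on qubit 0, then CNOT 0 -> 1
bell = apply_gate(init_state(2), hadamard(), qubit=0)
bell = apply_gate(bell, cnot(), control=0, target=1)
print("\nBell state amplitudes:", np.round(bell.amplitudes.real, 8))
print("(only |00> and |11> survive: the qubits are perfectly correlated)")

# Parameter-shift gradient of <Z> after RY(theta)|0>, which is cos(theta);
# the rule evaluates the circuit at theta +/- pi/2 and is exact, not a
# finite-difference approximation.


def observable(angles):
    s = apply_gate(init_state(1), rotation_y(angles[0]), qubit=0)
    return expectation_z(s, 0)


theta = np.pi / 3
grad = parameter_shift_gradient(observable, [theta], 0)
print(f"\nd<Z>/dtheta at theta=pi/3: {grad:.10f}")
print(f"analytic -sin(pi/3):       {-np.sin(theta):.10f}")
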