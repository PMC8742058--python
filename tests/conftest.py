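import numpy as np
import pytest

from qmarkush.encoding import build_code_table
from qmarkush.grover import grover_circuit
from qmarkush.oracle import build_intersection_oracle, build_patent_oracle


@pytest.fixture(scope="session")
def reference_table():
    """The reference two-bit code table: C -> 00, O -> 10, empty -> 11."""
    return build_code_table(["C", "O"], assignments={"C": "00", "O": "10"})


@pytest.fixture(scope="session")
def two_qubit_oracle():
    """Intersection oracle of the marked sets {11, 00} and {00}."""
    return build_intersection_oracle(
        build_patent_oracle({"11", "00"}, 2, n_data=2),
        build_patent_oracle({"00"}, 3, n_data=2),
    )


@pytest.fixture(scope="session")
def two_qubit_comparison_circuit(two_qubit_oracle):
    """The full one-iteration Grover circuit of the two-data-qubit case."""
    return grover_circuit(two_qubit_oracle, 1)


def random_circuit(rng: np.random.Generator, n_qubits: int, n_gates: int):
    """A random circuit over the full gate alphabet, for oracle checks."""
    from qmarkush.circuit import Circuit

    c = Circuit(n_qubits)
    kinds_1q = ["h", "x", "z", "s", "sdg", "t", "tdg"]
    for _ in range(n_gates):
        choice = rng.integers(0, 10)
        if choice < 5:
            c.add(str(rng.choice(kinds_1q)), int(rng.integers(n_qubits)))
        elif choice < 7 and n_qubits >= 2:
            a, b = rng.choice(n_qubits, size=2, replace=False)
            c.add("cx" if choice == 5 else "cz", int(a), int(b))
        elif choice < 8:
            c.add("p", int(rng.integers(n_qubits)), param=float(rng.uniform(-np.pi, np.pi)))
        elif n_qubits >= 3:
            k = int(rng.integers(2, n_qubits))
            qs = rng.choice(n_qubits, size=k + 1, replace=False)
            c.add("mcx" if choice == 8 else "mcz", *map(int, qs))
        else:
            c.add("x", int(rng.integers(n_qubits)))
    return c
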