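"""Gate/circuit data model with exact statevector simulation.

Conventions
-----------
Qubit 0 is the most significant bit of the basis index: the register is
laid out data-qubits-first (qubit 0 carries the leftmost bit of the encoded
bitstring), ancillas after.  A dense statevector over up to ~14 qubits is
supported; anything larger is rejected.

Supported gate kinds: ``h x z s sdg t tdg`` (fixed single-qubit), ``p``
(phase gate diag(1, e^{i theta})), ``cx cz`` (two-qubit), ``mcx mcz``
(multi-controlled, controls listed before the target) and ``u`` (explicit
unitary matrix on its qubits).
"""

from __future__ import annotations

import cmath
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Gate",
    "Circuit",
    "Statevector",
    "apply_gate",
    "simulate",
    "inverse",
    "unitary_of",
    "decompose_mcx",
    "decompose_circuit",
    "count_gates",
    "to_qasm",
    "from_qasm",
]

MAX_QUBITS = 14

_SQRT2 = 1.0 / math.sqrt(2.0)

_FIXED_1Q: dict[str, np.ndarray] = {
    "h": np.array([[_SQRT2, _SQRT2], [_SQRT2, -_SQRT2]], dtype=complex),
    "x": np.array([[0, 1], [1, 0]], dtype=complex),
    "z": np.array([[1, 0], [0, -1]], dtype=complex),
    "s": np.array([[1, 0], [0, 1j]], dtype=complex),
    "sdg": np.array([[1, 0], [0, -1j]], dtype=complex),
    "t": np.array([[1, 0], [0, cmath.exp(1j * math.pi / 4)]], dtype=complex),
    "tdg": np.array([[1, 0], [0, cmath.exp(-1j * math.pi / 4)]], dtype=complex),
}

_SELF_ADJOINT = {"h", "x", "z", "cx", "cz", "mcx", "mcz"}
_ADJOINT_PAIRS = {"s": "sdg", "sdg": "s", "t": "tdg", "tdg": "t"}

_KINDS_1Q = set(_FIXED_1Q) | {"p"}


@dataclass(frozen=True)
class Gate:
    """One gate: a kind, the qubits it acts on (controls before target for
    controlled kinds) and, for kind ``p``/``u``, its parameter/matrix."""

    kind: str
    qubits: tuple[int, ...]
    param: float | None = None
    matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.qubits)) != len(self.qubits):
            raise ValueError(f"repeated qubit in gate {self.kind} {self.qubits}")
        if self.kind in _KINDS_1Q and len(self.qubits) != 1:
            raise ValueError(f"{self.kind} acts on exactly one qubit")
        if self.kind in ("cx", "cz") and len(self.qubits) != 2:
            raise ValueError(f"{self.kind} acts on exactly two qubits")
        if self.kind in ("mcx", "mcz") and len(self.qubits) < 2:
            raise ValueError(f"{self.kind} needs at least one control")
        if self.kind == "p" and self.param is None:
            raise ValueError("p gate needs a parameter")
        if self.kind == "u":
            if self.matrix is None:
                raise ValueError("u gate needs a matrix")
            m = np.asarray(self.matrix, dtype=complex)
            k = len(self.qubits)
            if m.shape != (2**k, 2**k):
                raise ValueError(f"matrix shape {m.shape} does not fit {k} qubit(s)")
            if not np.allclose(m @ m.conj().T, np.eye(2**k), atol=1e-10):
                raise ValueError("matrix is not unitary within 1e-10")

    def adjoint(self) -> "Gate":
        if self.kind in _SELF_ADJOINT:
            return self
        if self.kind in _ADJOINT_PAIRS:
            return replace(self, kind=_ADJOINT_PAIRS[self.kind])
        if self.kind == "p":
            return replace(self, param=-self.param)
        if self.kind == "u":
            return replace(self, matrix=np.asarray(self.matrix).conj().T)
        raise ValueError(f"no adjoint for kind {self.kind!r}")

    def unitary(self) -> np.ndarray:
        """The gate's matrix on its own qubits (controls-first ordering)."""
        if self.kind in _FIXED_1Q:
            return _FIXED_1Q[self.kind].copy()
        if self.kind == "p":
            return np.array([[1, 0], [0, cmath.exp(1j * self.param)]], dtype=complex)
        if self.kind == "u":
            return np.asarray(self.matrix, dtype=complex).copy()
        k = len(self.qubits)
        m = np.eye(2**k, dtype=complex)
        if self.kind in ("cx", "mcx"):
            m[-2:, -2:] = np.array([[0, 1], [1, 0]])
        else:  # cz, mcz
            m[-1, -1] = -1
        return m


@dataclass
class Circuit:
    """Ordered gate list over ``n_data`` data qubits plus ancillas."""

    n_data: int
    n_ancilla: int = 0
    gates: list[Gate] = field(default_factory=list)

    @property
    def n_qubits(self) -> int:
        return self.n_data + self.n_ancilla

    def _check(self, gate: Gate) -> None:
        for q in gate.qubits:
            if not 0 <= q < self.n_qubits:
                raise ValueError(f"qubit {q} outside register of {self.n_qubits} qubits")

    def add(self, kind: str, *qubits: int, param: float | None = None,
            matrix: np.ndarray | None = None) -> "Circuit":
        g = Gate(kind=kind, qubits=tuple(qubits), param=param, matrix=matrix)
        self._check(g)
        self.gates.append(g)
        return self

    def append(self, gate: Gate) -> "Circuit":
        self._check(gate)
        self.gates.append(gate)
        return self

    def extend(self, other: "Circuit") -> "Circuit":
        if other.n_qubits > self.n_qubits:
            raise ValueError("cannot extend with a wider circuit")
        for g in other.gates:
            self.append(g)
        return self

    def inverse(self) -> "Circuit":
        return inverse(self)

    def copy(self) -> "Circuit":
        return Circuit(self.n_data, self.n_ancilla, list(self.gates))


def inverse(circuit: Circuit) -> Circuit:
    """Adjoint circuit: gates reversed, each replaced by its adjoint."""
    return Circuit(circuit.n_data, circuit.n_ancilla,
                   [g.adjoint() for g in reversed(circuit.gates)])


# ---------------------------------------------------------------------------
# statevector
# ---------------------------------------------------------------------------


@dataclass
class Statevector:
    """Pure state over ``2^(n_data+n_ancilla)`` amplitudes.

    The flat index is big-endian in qubit order: qubit 0 contributes the
    highest bit, so a data bitstring ``b`` with all ancillas zero sits at
    index ``int(b, 2) << n_ancilla``.
    """

    amplitudes: np.ndarray
    n_data: int
    n_ancilla: int = 0

    def __post_init__(self) -> None:
        n = self.n_data + self.n_ancilla
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex).reshape(2**n)

    @property
    def n_qubits(self) -> int:
        return self.n_data + self.n_ancilla

    @classmethod
    def zero(cls, n_data: int, n_ancilla: int = 0) -> "Statevector":
        amp = np.zeros(2 ** (n_data + n_ancilla), dtype=complex)
        amp[0] = 1.0
        return cls(amp, n_data, n_ancilla)

    @classmethod
    def basis(cls, data_index: int, n_data: int, n_ancilla: int = 0,
              ancilla_index: int = 0) -> "Statevector":
        amp = np.zeros(2 ** (n_data + n_ancilla), dtype=complex)
        amp[(data_index << n_ancilla) | ancilla_index] = 1.0
        return cls(amp, n_data, n_ancilla)

    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2

    def data_amplitude(self, data_index: int) -> complex:
        """Amplitude of a data basis state with all ancillas in |0>."""
        return complex(self.amplitudes[data_index << self.n_ancilla])

    def data_probabilities(self) -> np.ndarray:
        """Marginal distribution over the data register."""
        p = self.probabilities().reshape(2**self.n_data, 2**self.n_ancilla)
        return p.sum(axis=1)

    def ancilla_excited_probability(self) -> float:
        """Total probability on states with any ancilla in |1>."""
        if self.n_ancilla == 0:
            return 0.0
        p = self.probabilities().reshape(2**self.n_data, 2**self.n_ancilla)
        return float(p[:, 1:].sum())


def apply_gate(state: Statevector, gate: Gate) -> Statevector:
    """Apply one gate; identity on all other qubits.  Returns a new state."""
    n = state.n_qubits
    for q in gate.qubits:
        if not 0 <= q < n:
            raise ValueError(f"qubit {q} outside register of {n} qubits")
    arr = _apply_raw(state.amplitudes, n, gate)
    return Statevector(arr, state.n_data, state.n_ancilla)


def _apply_raw(flat: np.ndarray, n: int, gate: Gate) -> np.ndarray:
    """Kernel: apply a gate to a flat amplitude array (axis q <-> qubit q)."""
    psi = flat.reshape((2,) * n).copy()
    qs = list(gate.qubits)
    k = len(qs)
    if gate.kind in ("x", "cx", "mcx") or (gate.kind in ("z", "cz", "mcz")):
        moved = np.moveaxis(psi, qs, range(k))
        if gate.kind in ("x", "cx", "mcx"):
            sub = moved[(1,) * (k - 1)]  # controls fixed to |1>, target is axis 0 of sub
            sub[...] = sub[::-1].copy()
        else:
            moved[(1,) * k] *= -1.0
        return psi.reshape(-1)
    u = gate.unitary()
    moved = np.moveaxis(psi, qs, range(k))
    res = (u @ moved.reshape(2**k, -1)).reshape(moved.shape)
    return np.moveaxis(res, range(k), qs).reshape(-1).copy()


def simulate(circuit: Circuit, initial: Statevector | None = None) -> Statevector:
    """Exact left-to-right statevector simulation."""
    if circuit.n_qubits > MAX_QUBITS:
        raise ValueError(
            f"{circuit.n_qubits} qubits exceeds the dense-statevector cap of {MAX_QUBITS}"
        )
    if initial is None:
        state = Statevector.zero(circuit.n_data, circuit.n_ancilla)
    else:
        if initial.n_qubits != circuit.n_qubits:
            raise ValueError("initial state register size does not match circuit")
        state = Statevector(initial.amplitudes.copy(), initial.n_data, initial.n_ancilla)
    arr = state.amplitudes
    for g in circuit.gates:
        arr = _apply_raw(arr, circuit.n_qubits, g)
    return Statevector(arr, circuit.n_data, circuit.n_ancilla)


def unitary_of(circuit: Circuit) -> np.ndarray:
    """Full 2^n x 2^n unitary of a circuit (brute force; n <= 10)."""
    n = circuit.n_qubits
    if n > 10:
        raise ValueError("unitary_of is limited to 10 qubits")
    dim = 2**n
    cols = np.eye(dim, dtype=complex)
    out = np.empty((dim, dim), dtype=complex)
    for j in range(dim):
        arr = cols[:, j].copy()
        for g in circuit.gates:
            arr = _apply_raw(arr, n, g)
        out[:, j] = arr
    return out


# ---------------------------------------------------------------------------
# MCX decomposition
# ---------------------------------------------------------------------------


def _toffoli_gates(a: int, b: int, c: int) -> list[Gate]:
    """Textbook CCX decomposition: 9 single-qubit gates and 6 CNOTs."""
    G = Gate
    return [
        G("h", (c,)),
        G("cx", (b, c)),
        G("tdg", (c,)),
        G("cx", (a, c)),
        G("t", (c,)),
        G("cx", (b, c)),
        G("tdg", (c,)),
        G("cx", (a, c)),
        G("t", (b,)),
        G("t", (c,)),
        G("h", (c,)),
        G("cx", (a, b)),
        G("t", (a,)),
        G("tdg", (b,)),
        G("cx", (a, b)),
    ]


def _mcz_phase_gates(qubits: Sequence[int]) -> list[Gate]:
    """Ancilla-free C^{m-1}Z via parity phase gadgets.

    Expands the product x_1...x_m over XOR parities: for every nonempty
    subset S a phase ``pi * (-1)^{|S|+1} / 2^{m-1}`` is applied to the
    parity of S (CNOT chain in, phase gate, chain out).  Exact, no global
    phase residue.
    """
    m = len(qubits)
    base = math.pi / 2 ** (m - 1)
    gates: list[Gate] = []
    for mask in range(1, 2**m):
        subset = [qubits[i] for i in range(m) if (mask >> i) & 1]
        theta = base * (1 if len(subset) % 2 == 1 else -1)
        tgt = subset[-1]
        for q in subset[:-1]:
            gates.append(Gate("cx", (q, tgt)))
        gates.append(Gate("p", (tgt,), param=theta))
        for q in reversed(subset[:-1]):
            gates.append(Gate("cx", (q, tgt)))
    return gates


def _mcx_gates(qubits: Sequence[int]) -> list[Gate]:
    """MCX (controls + target) over 1q + CNOT gates."""
    qs = list(qubits)
    n_controls = len(qs) - 1
    if n_controls == 0:
        return [Gate("x", (qs[0],))]
    if n_controls == 1:
        return [Gate("cx", tuple(qs))]
    if n_controls == 2:
        return _toffoli_gates(*qs)
    t = qs[-1]
    return [Gate("h", (t,))] + _mcz_phase_gates(qs) + [Gate("h", (t,))]


def decompose_mcx(n_controls: int) -> Circuit:
    """Decompose an MCX with the given number of controls into single-qubit
    gates and CNOTs on ``n_controls + 1`` qubits (controls first)."""
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    c = Circuit(n_controls + 1)
    c.gates = _mcx_gates(range(n_controls + 1))
    return c


def decompose_circuit(circuit: Circuit) -> Circuit:
    """Expand every multi-qubit gate into single-qubit gates and CNOTs."""
    out = Circuit(circuit.n_data, circuit.n_ancilla)
    for g in circuit.gates:
        if g.kind in _KINDS_1Q or g.kind == "cx" or (g.kind == "u" and len(g.qubits) == 1):
            out.append(g)
        elif g.kind == "cz":
            a, b = g.qubits
            out.add("h", b)
            out.add("cx", a, b)
            out.add("h", b)
        elif g.kind == "mcx":
            for gg in _mcx_gates(g.qubits):
                out.append(gg)
        elif g.kind == "mcz":
            if len(g.qubits) == 2:
                a, b = g.qubits
                out.add("h", b)
                out.add("cx", a, b)
                out.add("h", b)
            else:
                for gg in _mcz_phase_gates(g.qubits):
                    out.append(gg)
        else:
            raise ValueError(f"cannot decompose gate kind {g.kind!r} on {len(g.qubits)} qubits")
    return out


def count_gates(circuit: Circuit) -> tuple[int, int]:
    """(single-qubit count, CNOT count); rejects undecomposed gates."""
    n1 = ncx = 0
    for g in circuit.gates:
        if g.kind == "cx":
            ncx += 1
        elif g.kind in _KINDS_1Q or (g.kind == "u" and len(g.qubits) == 1):
            n1 += 1
        else:
            raise ValueError(
                f"undecomposed multi-qubit gate {g.kind!r}; run decompose_circuit first"
            )
    return n1, ncx


# ---------------------------------------------------------------------------
# OpenQASM 2.0
# ---------------------------------------------------------------------------

_QASM_SIMPLE = {"h", "x", "z", "s", "sdg", "t", "tdg", "cx", "cz", "ccx"}


def to_qasm(circuit: Circuit) -> str:
    """OpenQASM 2.0 text for circuits over {h,x,z,s,sdg,t,tdg,p,cx,cz,mcx}.

    A two-control ``mcx`` is emitted as ``ccx``; wider ``mcx``/``mcz`` gates
    are expanded into the supported set first.
    """
    lines = ['OPENQASM 2.0;', 'include "qelib1.inc";', f"qreg q[{circuit.n_qubits}];"]

    def emit(g: Gate) -> None:
        args = ",".join(f"q[{q}]" for q in g.qubits)
        if g.kind == "p":
            lines.append(f"u1({g.param!r}) {args};")
        elif g.kind == "mcx" and len(g.qubits) == 3:
            lines.append(f"ccx {args};")
        elif g.kind in ("mcx", "mcz"):
            sub = (
                _mcx_gates(g.qubits) if g.kind == "mcx" else _mcz_phase_gates(g.qubits)
            )
            for gg in sub:
                emit(gg)
        elif g.kind in _QASM_SIMPLE:
            lines.append(f"{g.kind} {args};")
        else:
            raise ValueError(f"gate kind {g.kind!r} has no OpenQASM export")

    for g in circuit.gates:
        emit(g)
    return "\n".join(lines) + "\n"


_QASM_LINE = re.compile(r"^(\w+)\s*(?:\(([^)]*)\))?\s+(.*);$")
_QASM_ARG = re.compile(r"q\[(\d+)\]")


def from_qasm(text: str) -> Circuit:
    """Parse OpenQASM 2.0 restricted to the gate set written by to_qasm."""
    circuit: Circuit | None = None
    for raw in text.splitlines():
        line = raw.split("//", 1)[0].strip()
        if not line or line.startswith(("OPENQASM", "include")):
            continue
        m = re.match(r"^qreg\s+q\[(\d+)\];$", line)
        if m:
            circuit = Circuit(int(m.group(1)))
            continue
        m = _QASM_LINE.match(line)
        if not m or circuit is None:
            raise ValueError(f"cannot parse QASM line {raw!r}")
        name, param, args = m.groups()
        qubits = tuple(int(q) for q in _QASM_ARG.findall(args))
        if name == "u1":
            circuit.add("p", *qubits, param=float(param))
        elif name == "ccx":
            circuit.add("mcx", *qubits)
        elif name in _QASM_SIMPLE:
            circuit.add(name, *qubits)
        else:
            raise ValueError(f"unsupported QASM gate {name!r}")
    if circuit is None:
        raise ValueError("no qreg declaration found")
    return circuit
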