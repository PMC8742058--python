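"""Patent-membership oracles and the two-ancilla intersection oracle.

A patent oracle computes the membership indicator ``f_P(x) = [x in marked]``
into an ancilla by XOR: each marked bitstring is recognized by conjugating
an MCX with X gates on the data qubits whose bit is 0.  Two patent oracles
joined by a controlled-Z between their indicator ancillas phase-flip
exactly the states claimed by both patents (phase kickback); reversing the
marking circuits afterwards restores both ancillas to |0> so the data
register stays disentangled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .circuit import Circuit, inverse

__all__ = [
    "PatentOracle",
    "IntersectionOracle",
    "mark_state",
    "build_patent_oracle",
    "build_intersection_oracle",
    "uncompute_garbage",
]


@dataclass(frozen=True)
class PatentOracle:
    """Circuit computing |x>|a> -> |x>|a XOR f_P(x)> for a marked set."""

    marked: frozenset[str]
    target_ancilla: int
    n_data: int
    circuit: Circuit


@dataclass(frozen=True)
class IntersectionOracle:
    """Diagonal circuit: |x>|00> -> (-1)^{f_{M∩K}(x)} |x>|00>."""

    marked_intersection: frozenset[str]
    n_data: int
    circuit: Circuit


def _check_bits(bits: str) -> None:
    if not bits or set(bits) - {"0", "1"}:
        raise ValueError(f"invalid bitstring {bits!r}")


def mark_state(bits: str, target_ancilla: int) -> Circuit:
    """Flip the ancilla exactly when the data register equals ``bits``.

    X gates on every data qubit whose bit is 0, an MCX with all data qubits
    as controls onto the ancilla, then the same X gates to restore the data.
    """
    _check_bits(bits)
    n_data = len(bits)
    if target_ancilla < n_data:
        raise ValueError("target_ancilla must lie beyond the data register")
    c = Circuit(n_data, target_ancilla - n_data + 1)
    zeros = [i for i, b in enumerate(bits) if b == "0"]
    for q in zeros:
        c.add("x", q)
    c.add("mcx", *range(n_data), target_ancilla)
    for q in zeros:
        c.add("x", q)
    return c


def build_patent_oracle(marked: set[str] | frozenset[str], target_ancilla: int,
                        n_data: int | None = None) -> PatentOracle:
    """XOR-indicator oracle for an explicit marked set.

    Marking blocks are emitted in lexicographic order (they commute, the
    order is fixed only for determinism).  An empty set gives the identity.
    """
    marked = frozenset(marked)
    widths = {len(b) for b in marked}
    if len(widths) > 1:
        raise ValueError(f"marked bitstrings have mixed widths {sorted(widths)}")
    if n_data is None:
        if not marked:
            raise ValueError("n_data required for an empty marked set")
        (n_data,) = widths
    elif widths and widths != {n_data}:
        raise ValueError(f"bitstring width {widths} does not match n_data={n_data}")
    if target_ancilla < n_data:
        raise ValueError("target_ancilla must lie beyond the data register")
    c = Circuit(n_data, target_ancilla - n_data + 1)
    for bits in sorted(marked):
        c.extend(mark_state(bits, target_ancilla))
    return PatentOracle(marked=marked, target_ancilla=target_ancilla,
                        n_data=n_data, circuit=c)


def build_intersection_oracle(oracle_m: PatentOracle,
                              oracle_k: PatentOracle) -> IntersectionOracle:
    """Join two patent oracles into a phase oracle for their intersection.

    Compute both indicators, apply CZ between the two indicator ancillas
    (the Toffoli-free trick: a CZ needs no extra output qubit), then reverse
    both computations so every ancilla returns to |0>.
    """
    if oracle_m.n_data != oracle_k.n_data:
        raise ValueError("patent oracles have different data widths")
    if oracle_m.target_ancilla == oracle_k.target_ancilla:
        raise ValueError("patent oracles share the same target ancilla")
    n_data = oracle_m.n_data
    n_ancilla = max(oracle_m.target_ancilla, oracle_k.target_ancilla) - n_data + 1
    c = Circuit(n_data, n_ancilla)
    c.extend(oracle_m.circuit)
    c.extend(oracle_k.circuit)
    c.add("cz", oracle_m.target_ancilla, oracle_k.target_ancilla)
    c.extend(inverse(oracle_k.circuit))
    c.extend(inverse(oracle_m.circuit))
    return IntersectionOracle(
        marked_intersection=oracle_m.marked & oracle_k.marked,
        n_data=n_data,
        circuit=c,
    )


def uncompute_garbage(compute_circuit: Circuit,
                      f_register: list[int],
                      garbage_register: list[int],
                      out_register: list[int]) -> Circuit:
    """Clean-ancilla pattern: V_f |x,0,0> = |x,f(x),g(x)> becomes
    U_f |x,0,0,0> = |x,0,0,f(x)>.

    Compute, CNOT-copy the f register onto the out register bitwise, then
    apply the inverse computation so f- and garbage-registers end at zero.
    """
    regs = f_register + garbage_register + out_register
    if len(set(regs)) != len(regs):
        raise ValueError("f, garbage and out registers must not overlap")
    if len(out_register) != len(f_register):
        raise ValueError("out register must match the f register width")
    for q in f_register + garbage_register:
        if q >= compute_circuit.n_qubits:
            raise ValueError(f"register qubit {q} outside the compute circuit")
    n_qubits = max([compute_circuit.n_qubits - 1, *regs]) + 1
    c = Circuit(compute_circuit.n_data, n_qubits - compute_circuit.n_data)
    c.extend(compute_circuit)
    for src, dst in zip(f_register, out_register):
        c.add("cx", src, dst)
    c.extend(inverse(compute_circuit))
    return c
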