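"""Amplitude amplification around the patent-intersection oracle.

Standard Grover search: prepare the uniform superposition over all N = 2^n
encoded compounds, then repeat (intersection oracle, diffusion) k times
with k = floor(pi/4 * sqrt(N/M)) for M solutions.  After k iterations each
of the M marked compounds carries amplitude sin((2k+1) * arcsin(sqrt(M/N)))
/ sqrt(M).  The end-to-end pipeline enumerates both patents' claim
languages, expands alternative SMILES notations, encodes them, runs the
search and verifies the measured candidates classically against both claim
sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import Circuit, Statevector, simulate
from .encoding import (
    CodeTable,
    MarkushPatent,
    alternative_notations,
    decode_bitstring,
    encode_smiles,
    enumerate_claims,
    tokenize,
)
from .oracle import IntersectionOracle, build_intersection_oracle, build_patent_oracle

__all__ = [
    "GroverPlan",
    "GroverResult",
    "diffusion",
    "iteration_count",
    "run_grover",
    "compare_patents",
    "sample_counts",
    "success_amplitude",
]


@dataclass(frozen=True)
class GroverPlan:
    """Search-space size, solution count and iteration schedule."""

    n_data: int
    M: int
    k: int

    def __post_init__(self) -> None:
        if not 0 <= self.M <= self.N:
            raise ValueError("need 0 <= M <= N")
        if self.k < 0:
            raise ValueError("k must be >= 0")

    @property
    def N(self) -> int:
        return 2**self.n_data


@dataclass
class GroverResult:
    """Final state, measurement statistics and verified overlaps."""

    plan: GroverPlan
    amplitudes: Statevector
    probabilities: np.ndarray  # over the data register
    counts: dict[str, int]
    overlap_compounds: list[str] = field(default_factory=list)
    no_solution: bool = False

    def report(self, table: CodeTable | None = None) -> pd.DataFrame:
        """Per-basis-state table (index, bitstring, decoded SMILES,
        amplitude, probability, counts, verified flag)."""
        n = self.plan.n_data
        rows = []
        for idx in range(2**n):
            bits = format(idx, f"0{n}b")
            smiles = ""
            if table is not None:
                try:
                    smiles = decode_bitstring(bits, table)
                except (ValueError, KeyError):
                    smiles = ""
            amp = self.amplitudes.data_amplitude(idx)
            rows.append(
                {
                    "basis_index": idx,
                    "bitstring": bits,
                    "decoded_smiles": smiles,
                    "amplitude": round(amp.real, 9) if abs(amp.imag) < 1e-9 else complex(amp),
                    "probability": float(self.probabilities[idx]),
                    "counts": self.counts.get(bits, 0),
                    "verified_overlap": smiles in self.overlap_compounds and smiles != "",
                }
            )
        return pd.DataFrame(rows)


def diffusion(n_data: int) -> Circuit:
    """Reflection about the uniform state: H/X conjugated multi-controlled Z.

    Equals ``2|s><s| - I`` exactly: the bare H/X/MCZ/X/H sandwich realizes
    the negative of the reflection, so a compensating global phase of -1
    (an X,Z,X,Z sequence on qubit 0) is appended; marked-state amplitudes
    then match the closed form with their sign for every iteration count.
    """
    if n_data < 1:
        raise ValueError("n_data must be >= 1")
    c = Circuit(n_data)
    for q in range(n_data):
        c.add("h", q)
    for q in range(n_data):
        c.add("x", q)
    if n_data == 1:
        c.add("z", 0)
    else:
        c.add("mcz", *range(n_data))
    for q in range(n_data):
        c.add("x", q)
    for q in range(n_data):
        c.add("h", q)
    for kind in ("x", "z", "x", "z"):
        c.add(kind, 0)
    return c


def success_amplitude(N: int, M: int, k: int) -> float:
    """Closed-form per-target amplitude after k iterations."""
    theta = math.asin(math.sqrt(M / N))
    return math.sin((2 * k + 1) * theta) / math.sqrt(M)


def iteration_count(N: int, M: int) -> int:
    """Standard Grover schedule k = floor((pi/4) sqrt(N/M)).

    Falls back to k = 0 when the uniform superposition already succeeds
    with at least the post-iteration probability (e.g. M = N).
    """
    if not 1 <= M <= N:
        raise ValueError("need 1 <= M <= N (the no-solution case is handled upstream)")
    k = math.floor(math.pi / 4 * math.sqrt(N / M))
    if k > 0:
        p_uniform = M / N
        p_k = M * success_amplitude(N, M, k) ** 2
        if p_uniform >= p_k:
            k = 0
    return k


def sample_counts(probabilities: np.ndarray, shots: int, seed: int) -> np.ndarray:
    """Reproducible multinomial draw; counts sum to shots."""
    p = np.asarray(probabilities, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(shots, p / p.sum())


def grover_circuit(oracle: IntersectionOracle, k: int) -> Circuit:
    """Full search circuit: Hadamard layer then k x (oracle, diffusion)."""
    n_data = oracle.n_data
    c = Circuit(n_data, oracle.circuit.n_ancilla)
    for q in range(n_data):
        c.add("h", q)
    diff = diffusion(n_data)
    for _ in range(k):
        c.extend(oracle.circuit)
        c.extend(diff)
    return c


def run_grover(oracle: IntersectionOracle, plan: GroverPlan, shots: int = 1024,
               seed: int = 0) -> GroverResult:
    """Execute the search exactly and sample measurement counts.

    Measurement reads the data qubits only; in the noiseless circuit the
    ancillas are exactly |00> at the end, so the data marginal carries the
    whole distribution.
    """
    if oracle.n_data != plan.n_data:
        raise ValueError("oracle and plan disagree on n_data")
    circuit = grover_circuit(oracle, plan.k)
    final = simulate(circuit)
    probs = final.data_probabilities()
    drawn = sample_counts(probs, shots, seed)
    n = plan.n_data
    counts = {format(i, f"0{n}b"): int(c) for i, c in enumerate(drawn) if c}
    return GroverResult(plan=plan, amplitudes=final, probabilities=probs, counts=counts)


def _expand_notations(claims, tokens):
    out: set[str] = set()
    for s in claims:
        try:
            out |= alternative_notations(s, tokens)
        except ValueError:
            out.add(s)  # branched/ring strings: keep the literal notation
    return out


def compare_patents(
    patent_m: MarkushPatent,
    patent_k: MarkushPatent,
    table: CodeTable,
    shots: int = 1024,
    seed: int = 0,
    tokens: list[str] | None = None,
    max_len: int | None = None,
) -> GroverResult:
    """End-to-end comparison of two Markush patents.

    Enumerate both claim languages, expand alternative notations, encode
    with a shared maximum length, build the intersection oracle, run the
    Grover schedule, and verify every measured high-probability candidate
    classically against both claim sets.  The solution count M is taken
    from the classical enumerations (desk scale); when the intersection is
    empty no amplification is run and the result carries a no-solution
    flag.
    """
    claims_m = _expand_notations(enumerate_claims(patent_m), tokens)
    claims_k = _expand_notations(enumerate_claims(patent_k), tokens)
    if not claims_m or not claims_k:
        raise ValueError("a patent claims no compounds")
    longest = max(len(tokenize(s, tokens)) for s in claims_m | claims_k)
    if max_len is None:
        max_len = longest
    elif max_len < longest:
        raise ValueError(f"max_len={max_len} below the longest claim ({longest} symbols)")
    n_data = max_len * table.bits_per_symbol

    marked_m = {encode_smiles(s, table, max_len, tokens).bitstring for s in claims_m}
    marked_k = {encode_smiles(s, table, max_len, tokens).bitstring for s in claims_k}
    oracle = build_intersection_oracle(
        build_patent_oracle(marked_m, n_data, n_data=n_data),
        build_patent_oracle(marked_k, n_data + 1, n_data=n_data),
    )
    M = len(oracle.marked_intersection)
    N = 2**n_data
    k = iteration_count(N, M) if M else 0
    plan = GroverPlan(n_data=n_data, M=M, k=k)
    result = run_grover(oracle, plan, shots=shots, seed=seed)
    result.no_solution = M == 0

    # decode amplified states and verify against both claim languages
    threshold = 0.4 / M if M else 2.0 / N
    candidates = [i for i, p in enumerate(result.probabilities) if p >= threshold]
    verified: list[str] = []
    for idx in candidates:
        bits = format(idx, f"0{n_data}b")
        try:
            smiles = decode_bitstring(bits, table)
        except (ValueError, KeyError):
            continue
        if smiles in claims_m and smiles in claims_k:
            verified.append(smiles)
    result.overlap_compounds = sorted(verified)
    return result
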