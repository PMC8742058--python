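# Methods

## Claim grammars and counting

A Markush patent is modeled as a template grammar: a `core` string with
`{Name}` placeholders, a map of R-group production rules (each production
again a template), and terminal choice lists for the leaf variation
symbol.  The reference graph must be acyclic, which makes the claimed
language finite; cycles are rejected at construction time with the cycle
named.  Enumeration expands depth-first in production order (later
template positions varying fastest) and deduplicates strings;
`count_claims` counts *derivations* by dynamic programming (product over
template positions, sum over productions).  The two agree exactly when no
two derivations collide on the same string — with a single terminal
choice, nested grammars do collide (five derivations of the nested
two-level example collapse onto two strings), and this divergence is
deliberate: the DP mirrors how claim counts are quoted, while enumeration
feeds the oracle, where duplicates would be wrong.

## Encoding

`build_code_table` assigns codes in input order with width
`⌈log₂(n_symbols+1)⌉` and reserves the all-ones code for the padding
symbol.  The worked examples force `C→00`, `O→10`, `empty→11`, which is
not the input-order assignment, so explicit per-symbol code overrides are
accepted; the remaining code `01` is free for a user-chosen third symbol.
Encoded strings are padded with the empty code to a shared maximum symbol
count; the concatenated bitstring read left-to-right is the big-endian
basis index.  Decoding enforces that padding occurs only as a contiguous
suffix.  Tokenization is per character by default; a token list enables
multi-character SMILES tokens such as `Cl`.

One molecule admits several SMILES strings.  The built-in notation
expander handles unbranched chains (string plus token-wise reversal) and
rejects rings/branches; a pluggable `expander` hook accepts a general
enumerator.  The comparison pipeline folds all notations of every claim
into the oracle, so the search is over notations, and verification maps
back to molecules.

## Simulator conventions

Qubit 0 is the most significant bit of the basis index; data qubits come
first, ancillas after, so a data string `b` with clean ancillas sits at
flat index `int(b,2) << n_ancilla` and any excited ancilla pushes a state
into the "beyond the data register" band when indices are reported
ancilla-high.  The dense statevector kernel applies gates by tensor-axis
manipulation; multi-controlled X/Z are applied as permutations/diagonals
directly, so wide oracles cost little.  The register is capped at 14
qubits — the package targets desk-scale verification, not large-scale
emulation.

MCX decomposition: one control is a CNOT; two controls use the textbook
9-single-qubit/6-CNOT Toffoli network; three or more controls go through
an exact ancilla-free parity-phase construction of the multi-controlled-Z
(one phase gate per non-empty control subset, conjugated by CNOT parity
chains) sandwiched between Hadamards.  The construction is exact including
global phase.  It is not gate-count optimal — gate counts for MCX
constructions depend heavily on the synthesis convention and are not
comparable across implementations; this implementation's counts are
pinned as regression values instead.

## Oracles

`mark_state` recognizes one bitstring by X-conjugating an MCX over all
data qubits ("apply X where the bit is 0").  A patent oracle concatenates
marking blocks in lexicographic order — the blocks commute, so the order
is fixed purely for determinism.  The intersection oracle computes both
indicators, applies CZ between the two indicator ancillas (saving the
extra output qubit a Toffoli would need), and reverses both computations,
which provably restores the ancillas to |00⟩ for every basis state.  The
generic `uncompute_garbage` pattern (compute, CNOT-copy the answer,
uncompute) is provided for oracles built from classical reversible
circuits with scratch registers.

## Diffusion and the global phase

The diffusion operator is the reflection `2|s⟩⟨s| − I`.  The usual
H/X/MCZ/X/H sandwich realizes its *negative*; the phase is unobservable in
probabilities but flips the sign of final amplitudes for odd iteration
counts.  Since amplitude tables are part of this package's contract, an
explicit global-phase correction (X,Z,X,Z on qubit 0) is appended so the
closed form `sin((2k+1)θ)/√M` holds with its sign for every k.

## Iteration schedule and the no-solution case

`k = ⌊(π/4)√(N/M)⌋`, the standard-Grover choice, with a fallback to
`k = 0` when the uniform state already meets the post-iteration success
probability (e.g. `M = N`).  M is computed classically from the desk-scale
enumerations; quantum counting is out of scope.  When the claim languages
do not intersect (`M = 0`) no amplification is run: the pipeline reports
an empty overlap with a no-solution flag rather than amplifying noise,
and because every measured candidate is verified classically against both
claim languages, a false positive cannot be reported in any case.
Candidate states are those with probability at least `0.4/M` (or `2/N`
when `M = 0`), far above the non-target level and safely below the
amplified level at every reachable (N, M).

## Boolean compression

`simplify` computes prime implicants with Quine–McCluskey (via sympy's
`SOPform`) and then factors literals common to all terms; when each
residual term is a single literal the result is the AND-of-clauses form
`~A & ~C & (~B | ~D)`-style, otherwise the minimal sum-of-products is
returned.  Output is deterministic (terms and literals sorted by variable
order) and never has more literals than the input; equivalence is asserted
by truth table on every call.  Compilation maps single-literal clauses to
X-conjugated controls of one MCX; each OR clause gets a scratch ancilla
computed through De Morgan and uncomputed afterwards.  Sums of products
compile to XOR marking blocks when the terms are pairwise disjoint;
overlapping products (which prime implicants can produce) get one scratch
ancilla per term, OR-combined into the target and uncomputed — XOR blocks
would cancel on doubly-covered states.

## Noise model

Channels are applied after each gate of the 1q+CNOT-decomposed circuit on
the touched qubits only: depolarizing (the state of the touched qubit(s)
is replaced by the completely mixed state with probability `p_depol_1q` or
`p_depol_2q`), then thermal relaxation over the gate's duration
(amplitude damping with rate `1 − e^{−t/T1}` composed with enough pure
dephasing that coherences decay as `e^{−t/T2}`; `T2 ≤ 2T1` enforced).
Readout error is a per-qubit row-stochastic flip matrix applied to the
final outcome distribution.  Idle-qubit relaxation is omitted — a
documented simplification appropriate for the shallow circuits studied
here.  Density-matrix evolution is capped at 7 qubits, which covers the
two-data-qubit comparison circuit (4 qubits) with room to spare.

Each family has a scale factor multiplying its error *rate* (for thermal
noise the factor divides T1 and T2), so the one-family-at-a-time
halve/double protocol is `error_scaling_experiment`: only the chosen
family is enabled, its parameters are scaled by {0.5, 1, 2}, and
correctness — the fraction of shots on the known correct data outcome —
is averaged over 10 seeded repetitions of 1024 shots with a 95% CI.

The default model (`synthetic_vigo_like_model`) is **synthetic**: no real
calibration snapshot is bundled, so the defaults are chosen once as
plausible for a 2019-era five-qubit transmon chip such as ibmq_vigo
(T1 = 80 µs, T2 = 60 µs, 35 ns single-qubit and 300 ns CNOT durations,
depolarizing 0.15%/1.2%, readout flips 2%).  In this regime the per-gate
depolarizing error dominates the two-data-qubit circuit's error budget,
thermal relaxation is second, and readout barely matters — the qualitative
ordering the protocol is designed to expose.  Absolute correctness
percentages under this model are not comparable to any hardware run.

## Routing cost

`routing_cost` sums, over the two-qubit gates of the decomposed circuit,
the shortest-path length between the mapped physical qubits minus one —
a SWAP-equivalent overhead proxy, not a transpiler emulation.  On the
T-shaped five-qubit coupling graph (edges 0–1, 1–2, 1–3, 3–4) the mapping
that puts the heavily-coupled logical data qubits onto the
high-connectivity center (q0,q1,q2,q3 → 1,2,0,3) costs 13 excess hops on
the two-data-qubit comparison circuit versus 20 for the linear chain
mapping (→ 4,3,1,0), matching the observed advantage of
connectivity-aware placement.

## Synthetic fixtures: what they do and do not show

The fixture generator plants an exact overlap: claim strings are sampled
as unbranched chains by distinct reversal-equivalence classes, so
alternative-notation expansion cannot create accidental overlaps, and the
expected overlap is known by construction.  Presets rebuild the two
worked examples (marked sets {11,00} vs {00}; and the CC{R1}/O{R2} pair
whose overlap encodes to basis states 2 and 128 — the concrete R-group
members are synthetic stand-ins chosen to give two and three members
respectively and exactly that overlap).  Fixtures exercise encoding, oracle construction,
amplification and verification end to end, but they do not exercise real
SMILES chemistry: no rings, branches, aromaticity or canonicalization —
chemical validity is explicitly out of scope.

## Problem sizes and numerical choices

Default problem sizes keep everything at desk scale: 8 data + 2 ancilla
qubits for the headline simulation, 4 qubits for the noisy density-matrix
runs, 100 seeded fixtures (≤ 8 qubits each) for planted-recovery
properties.  Unitary equivalences are checked to 1e-9 after removing a
global phase where the construction has one; state norms and channel trace
preservation to 1e-10; oracle-equivalence checks are exhaustive and
restricted to ≤ 10 data qubits.  All sampling flows through
`numpy.random.default_rng` seeded per call, so every reported number is
reproducible bit for bit.

## Known limitations

- Dense statevector only (≤ 14 qubits); no tensor-network or trajectory
  fallback for larger registers.
- The claimed language must be finite (acyclic grammar) and M is obtained
  classically, which presumes the desk-scale enumeration is feasible;
  the quantum circuit itself does not depend on this shortcut.
- Alternative-notation enumeration ships only for unbranched chains.
- Gate counts are implementation-specific; no transpilation parity with
  external frameworks is attempted.
- Noise is Markovian, gate-local and calibration-free; crosstalk,
  leakage and idle decay are not modeled.
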