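"""Noisy density-matrix simulation and coupling-graph routing cost.

Three error families are modeled, mirroring the dominant error sources of
small superconducting devices:

* thermal relaxation — amplitude damping with rate ``1 - exp(-t/T1)``
  composed with pure dephasing so that coherences decay as ``exp(-t/T2)``
  over each gate's duration (physical only when ``T2 <= 2*T1``);
* depolarizing gate error — with probability p the touched qubit(s) are
  replaced by the completely mixed state;
* readout error — a per-qubit row-stochastic flip matrix applied to the
  final measurement distribution.

Each family carries a scale factor so a one-family-at-a-time x2 / x0.5
sensitivity sweep can be run.  No real calibration snapshot is bundled;
the shipped default model is synthetic, chosen to sit in the regime of a
2019-era five-qubit superconducting device.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .circuit import Circuit, Gate, decompose_circuit

__all__ = [
    "NoiseModel",
    "DensityMatrix",
    "CouplingGraph",
    "depolarizing_channel",
    "thermal_relaxation_channel",
    "apply_readout_error",
    "simulate_noisy",
    "noisy_probabilities",
    "error_scaling_experiment",
    "FAMILIES",
    "routing_cost",
    "synthetic_vigo_like_model",
    "vigo_coupling",
    "load_noise_model",
    "load_coupling_graph",
]

FAMILIES = ("thermal", "depolarizing", "readout")

MAX_DENSITY_QUBITS = 7


@dataclass(frozen=True)
class NoiseModel:
    """Error parameters for the three families plus per-family scale factors.

    Times share one unit with ``gate_durations`` (nanoseconds by
    convention).  ``readout`` is ``(p(read 1 | state 0), p(read 0 | state 1))``
    applied to every measured qubit.
    """

    p_depol_1q: float = 0.0
    p_depol_2q: float = 0.0
    t1: float = math.inf
    t2: float = math.inf
    gate_durations: dict[str, float] = field(
        default_factory=lambda: {"1q": 35.0, "cx": 300.0}
    )
    readout: tuple[float, float] = (0.0, 0.0)
    scale: dict[str, float] = field(
        default_factory=lambda: {f: 1.0 for f in FAMILIES}
    )

    def __post_init__(self) -> None:
        if self.t2 > 2.0 * self.t1:
            raise ValueError("unphysical relaxation times: T2 must be <= 2*T1")
        for p in (self.p_depol_1q, self.p_depol_2q, *self.readout):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for f in self.scale:
            if f not in FAMILIES:
                raise ValueError(f"unknown noise family {f!r}")

    # -- effective (scaled) parameters --------------------------------------

    def _clip(self, p: float) -> float:
        if p > 1.0:
            warnings.warn(f"scaled probability {p:.3g} clipped to 1", stacklevel=3)
            return 1.0
        return p

    def depol_1q(self) -> float:
        return self._clip(self.p_depol_1q * self.scale.get("depolarizing", 1.0))

    def depol_2q(self) -> float:
        return self._clip(self.p_depol_2q * self.scale.get("depolarizing", 1.0))

    def relaxation_times(self) -> tuple[float, float]:
        """T1, T2 with the thermal scale applied to the decay *rates*."""
        s = self.scale.get("thermal", 1.0)
        if s == 0.0:
            return math.inf, math.inf
        return self.t1 / s, self.t2 / s

    def readout_matrix(self) -> np.ndarray:
        s = self.scale.get("readout", 1.0)
        p01 = self._clip(self.readout[0] * s)
        p10 = self._clip(self.readout[1] * s)
        return np.array([[1 - p01, p01], [p10, 1 - p10]], dtype=float)

    def duration_of(self, gate: Gate) -> float:
        if gate.kind == "cx":
            return self.gate_durations.get("cx", 0.0)
        return self.gate_durations.get(gate.kind, self.gate_durations.get("1q", 0.0))

    def with_scale(self, family: str, factor: float) -> "NoiseModel":
        if family not in FAMILIES:
            raise ValueError(f"unknown noise family {family!r}")
        scale = dict(self.scale)
        scale[family] = factor
        return replace(self, scale=scale)

    def only_family(self, family: str) -> "NoiseModel":
        """Copy with every family except ``family`` switched off."""
        if family not in FAMILIES:
            raise ValueError(f"unknown noise family {family!r}")
        kw: dict = {}
        if family != "depolarizing":
            kw.update(p_depol_1q=0.0, p_depol_2q=0.0)
        if family != "thermal":
            kw.update(t1=math.inf, t2=math.inf)
        if family != "readout":
            kw.update(readout=(0.0, 0.0))
        return replace(self, **kw)


def synthetic_vigo_like_model() -> NoiseModel:
    """Synthetic stand-in for a five-qubit device calibration snapshot.

    The values are plausible for a 2019-era superconducting transmon chip
    (T1 ~ 80 us, T2 ~ 60 us, 35 ns single-qubit and 300 ns CNOT gates,
    ~0.15% / 1.2% depolarizing rates, 2% readout flips); they are not a
    real calibration snapshot.
    """
    return NoiseModel(
        p_depol_1q=0.0015,
        p_depol_2q=0.012,
        t1=80_000.0,
        t2=60_000.0,
        gate_durations={"1q": 35.0, "cx": 300.0},
        readout=(0.02, 0.02),
    )


# ---------------------------------------------------------------------------
# density matrix and channels
# ---------------------------------------------------------------------------


@dataclass
class DensityMatrix:
    """Mixed state as a trace-one Hermitian PSD matrix over 2^q states."""

    matrix: np.ndarray
    n_qubits: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=complex)
        dim = 2**self.n_qubits
        if self.matrix.shape != (dim, dim):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({dim}, {dim})")

    @classmethod
    def zero(cls, n_qubits: int) -> "DensityMatrix":
        m = np.zeros((2**n_qubits, 2**n_qubits), dtype=complex)
        m[0, 0] = 1.0
        return cls(m, n_qubits)

    def validate(self, atol: float = 1e-8) -> None:
        if abs(np.trace(self.matrix) - 1.0) > atol:
            raise ValueError("trace != 1")
        if not np.allclose(self.matrix, self.matrix.conj().T, atol=atol):
            raise ValueError("not Hermitian")
        if np.linalg.eigvalsh(self.matrix).min() < -atol:
            raise ValueError("negative eigenvalue")

    def probabilities(self) -> np.ndarray:
        p = np.real(np.diag(self.matrix)).copy()
        p[p < 0] = 0.0
        return p / p.sum()


def _tensor_apply(rho: np.ndarray, n: int, op: np.ndarray, qubits: list[int]) -> np.ndarray:
    """U rho U^dag with U acting on the named qubits (qubit 0 = MSB)."""
    k = len(qubits)
    t = rho.reshape((2,) * (2 * n))
    row_axes = qubits
    t = np.moveaxis(t, row_axes, range(k))
    t = (op @ t.reshape(2**k, -1)).reshape((2,) * (2 * n))
    t = np.moveaxis(t, range(k), row_axes)
    col_axes = [n + q for q in qubits]
    t = np.moveaxis(t, col_axes, range(k))
    t = (op.conj() @ t.reshape(2**k, -1)).reshape((2,) * (2 * n))
    t = np.moveaxis(t, range(k), col_axes)
    return t.reshape(2**n, 2**n)


def _apply_kraus(rho: np.ndarray, n: int, kraus: list[np.ndarray], qubits: list[int]) -> np.ndarray:
    return sum(_tensor_apply(rho, n, K, qubits) for K in kraus)


def _replace_with_mixed(rho: np.ndarray, n: int, qubits: list[int]) -> np.ndarray:
    """Partial-trace the named qubits out and tensor the mixed state back."""
    k = len(qubits)
    rest = [q for q in range(n) if q not in qubits]
    # axis q is qubit q's row index, axis n+q its column index
    perm = (
        list(qubits) + [n + q for q in qubits] + rest + [n + q for q in rest]
    )
    t = np.moveaxis(rho.reshape((2,) * (2 * n)), perm, range(2 * n))
    t = t.reshape(2**k, 2**k, 2 ** (n - k), 2 ** (n - k))
    traced = np.einsum("iijk->jk", t)
    mixed = np.eye(2**k, dtype=complex) / 2**k
    combined = np.einsum("ab,jk->abjk", mixed, traced).reshape((2,) * (2 * n))
    return np.moveaxis(combined, range(2 * n), perm).reshape(2**n, 2**n)


def depolarizing_channel(rho: DensityMatrix, p: float, qubits: list[int]) -> DensityMatrix:
    """With probability p, replace the named qubits by the fully mixed state."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p == 0.0:
        return DensityMatrix(rho.matrix.copy(), rho.n_qubits)
    mixed = _replace_with_mixed(rho.matrix, rho.n_qubits, list(qubits))
    return DensityMatrix((1 - p) * rho.matrix + p * mixed, rho.n_qubits)


def thermal_relaxation_channel(rho: DensityMatrix, t1: float, t2: float,
                               duration: float, qubit: int) -> DensityMatrix:
    """Amplitude damping (rate 1 - e^{-t/T1}) plus pure dephasing so the
    off-diagonals scale by e^{-t/T2}."""
    if t2 > 2.0 * t1:
        raise ValueError("unphysical relaxation times: T2 must be <= 2*T1")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if duration == 0 or (math.isinf(t1) and math.isinf(t2)):
        return DensityMatrix(rho.matrix.copy(), rho.n_qubits)
    gamma = 1.0 - math.exp(-duration / t1) if not math.isinf(t1) else 0.0
    ad = [
        np.array([[1, 0], [0, math.sqrt(1 - gamma)]], dtype=complex),
        np.array([[0, math.sqrt(gamma)], [0, 0]], dtype=complex),
    ]
    out = _apply_kraus(rho.matrix, rho.n_qubits, ad, [qubit])
    # residual dephasing: total off-diagonal factor e^{-t/T2}; amplitude
    # damping already contributes e^{-t/2T1}
    log_extra = (-duration / t2 if not math.isinf(t2) else 0.0) + (
        duration / (2 * t1) if not math.isinf(t1) else 0.0
    )
    lam = min(1.0, math.exp(log_extra))
    p_z = (1.0 - lam) / 2.0
    if p_z > 0:
        z = np.array([[1, 0], [0, -1]], dtype=complex)
        deph = [math.sqrt(1 - p_z) * np.eye(2, dtype=complex), math.sqrt(p_z) * z]
        out = _apply_kraus(out, rho.n_qubits, deph, [qubit])
    return DensityMatrix(out, rho.n_qubits)


def apply_readout_error(probabilities: np.ndarray, readout: np.ndarray | list[np.ndarray],
                        ) -> np.ndarray:
    """Mix an outcome distribution through per-qubit flip matrices.

    ``readout`` is a single 2x2 row-stochastic matrix (applied to every
    qubit) or a list with one matrix per qubit; entry [i, j] is
    p(read j | state i).
    """
    p = np.asarray(probabilities, dtype=float)
    n = int(round(math.log2(p.size)))
    if 2**n != p.size:
        raise ValueError("length of probabilities must be a power of 2")
    mats = [np.asarray(readout, dtype=float)] * n if np.ndim(readout) == 2 else [
        np.asarray(m, dtype=float) for m in readout
    ]
    if len(mats) != n:
        raise ValueError(f"need {n} readout matrices, got {len(mats)}")
    for m in mats:
        if m.shape != (2, 2) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9) or (m < -1e-12).any():
            raise ValueError("readout matrices must be 2x2 row-stochastic")
    t = p.reshape((2,) * n)
    for q, m in enumerate(mats):
        t = np.moveaxis(np.tensordot(m.T, np.moveaxis(t, q, 0), axes=1), 0, q)
    return t.reshape(-1)


def simulate_noisy(circuit: Circuit, noise: NoiseModel, shots: int = 1024,
                   seed: int = 0, measure_qubits: list[int] | None = None,
                   ) -> dict[str, int]:
    """Density-matrix simulation with per-gate noise insertion.

    The circuit is decomposed to single-qubit + CNOT gates; after each gate
    a depolarizing channel (1q or 2q rate) and thermal relaxation over the
    gate's duration act on the touched qubits, and the readout flip matrix
    perturbs the final measurement distribution before sampling.  Idle
    qubits do not relax (documented simplification).  Limited to
    ``2^7``-dimensional registers.
    """
    probs = noisy_probabilities(circuit, noise, measure_qubits)
    drawn = np.random.default_rng(seed).multinomial(shots, probs)
    width = int(round(math.log2(probs.size)))
    return {format(i, f"0{width}b"): int(c) for i, c in enumerate(drawn) if c}


def noisy_probabilities(circuit: Circuit, noise: NoiseModel,
                        measure_qubits: list[int] | None = None) -> np.ndarray:
    """Deterministic outcome distribution of the noisy circuit."""
    n = circuit.n_qubits
    if n > MAX_DENSITY_QUBITS:
        raise ValueError(
            f"{n} qubits exceeds the density-matrix cap of {MAX_DENSITY_QUBITS}"
        )
    dec = decompose_circuit(circuit)
    rho = DensityMatrix.zero(n)
    t1, t2 = noise.relaxation_times()
    for g in dec.gates:
        rho = DensityMatrix(_tensor_apply(rho.matrix, n, g.unitary(), list(g.qubits)), n)
        p = noise.depol_2q() if len(g.qubits) == 2 else noise.depol_1q()
        if p > 0:
            rho = depolarizing_channel(rho, p, list(g.qubits))
        dur = noise.duration_of(g)
        if dur > 0 and not (math.isinf(t1) and math.isinf(t2)):
            for q in g.qubits:
                rho = thermal_relaxation_channel(rho, t1, t2, dur, q)
    probs = rho.probabilities()
    probs = apply_readout_error(probs, noise.readout_matrix())
    if measure_qubits is not None:
        t = probs.reshape((2,) * n)
        keep = sorted(measure_qubits)
        drop = tuple(q for q in range(n) if q not in keep)
        t = t.sum(axis=drop)
        probs = t.reshape(-1)
    return probs / probs.sum()


def error_scaling_experiment(
    circuit: Circuit,
    noise: NoiseModel,
    family: str,
    correct_states: set[str],
    factors: tuple[float, ...] = (0.5, 1.0, 2.0),
    shots: int = 1024,
    repeats: int = 10,
    seed: int = 0,
    measure_qubits: list[int] | None = None,
) -> pd.DataFrame:
    """One-family-at-a-time error sensitivity sweep.

    For each scale factor, only the chosen family is enabled and its
    parameters are scaled; correctness is the fraction of shots landing on
    the known correct state(s), averaged over ``repeats`` seeded runs with
    a 95% confidence interval.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown noise family {family!r}; choose from {FAMILIES}")
    rows = []
    for fi, factor in enumerate(factors):
        model = noise.only_family(family).with_scale(family, factor)
        probs = noisy_probabilities(circuit, model, measure_qubits)
        width = int(round(math.log2(probs.size)))
        correct_idx = [int(s, 2) for s in correct_states]
        rng = np.random.default_rng(seed + 1000 * fi)
        fracs = []
        for _ in range(repeats):
            drawn = rng.multinomial(shots, probs)
            fracs.append(sum(drawn[i] for i in correct_idx) / shots)
        fracs = np.asarray(fracs)
        sem = fracs.std(ddof=1) / math.sqrt(repeats) if repeats > 1 else 0.0
        rows.append(
            {
                "family": family,
                "factor": factor,
                "mean_correct": float(fracs.mean()),
                "ci95": float(1.96 * sem),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coupling graphs and routing cost
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CouplingGraph:
    """Physical-qubit adjacency of a device."""

    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        declared = set(self.nodes)
        for a, b in self.edges:
            if a not in declared or b not in declared:
                raise ValueError(f"edge ({a}, {b}) references an undeclared node")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def vigo_coupling() -> CouplingGraph:
    """The five-qubit T-shaped layout: 0-1, 1-2, 1-3, 3-4."""
    return CouplingGraph(nodes=(0, 1, 2, 3, 4), edges=((0, 1), (1, 2), (1, 3), (3, 4)))


def routing_cost(circuit: Circuit, coupling: CouplingGraph,
                 mapping: dict[int, int]) -> int:
    """SWAP-equivalent overhead of running a circuit under a qubit mapping.

    Sum over two-qubit gates of (shortest physical path length between the
    mapped endpoints - 1); zero when every two-qubit gate touches adjacent
    physical qubits.  Multi-qubit gates are decomposed first.
    """
    phys = list(mapping.values())
    if len(set(phys)) != len(phys):
        raise ValueError("mapping must be injective")
    g = coupling.graph()
    for p in phys:
        if p not in g:
            raise ValueError(f"physical qubit {p} not in the coupling graph")
    dec = decompose_circuit(circuit)
    cost = 0
    for gate in dec.gates:
        if len(gate.qubits) != 2:
            continue
        a, b = (mapping[q] for q in gate.qubits)
        try:
            d = nx.shortest_path_length(g, a, b)
        except nx.NetworkXNoPath:
            raise ValueError(f"physical qubits {a} and {b} are disconnected") from None
        cost += d - 1
    return cost


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------


def load_noise_model(path: str) -> NoiseModel:
    """Read a YAML noise config (t1/t2/gate_durations/p_depol_*/readout/scale)."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    kw: dict = {}
    for key in ("p_depol_1q", "p_depol_2q", "t1", "t2"):
        if key in doc:
            kw[key] = float(doc[key])
    if "gate_durations" in doc:
        kw["gate_durations"] = {str(k): float(v) for k, v in doc["gate_durations"].items()}
    if "readout" in doc:
        kw["readout"] = tuple(float(v) for v in doc["readout"])
    if "scale" in doc:
        kw["scale"] = {str(k): float(v) for k, v in doc["scale"].items()}
    return NoiseModel(**kw)


def load_coupling_graph(path: str) -> CouplingGraph:
    """Read an edge-list text file (one ``a b`` pair per line, '#' comments)."""
    edges: list[tuple[int, int]] = []
    nodes: set[int] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            a, b = (int(x) for x in line.split())
            edges.append((a, b))
            nodes |= {a, b}
    return CouplingGraph(nodes=tuple(sorted(nodes)), edges=tuple(edges))
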