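"""Seeded synthetic patent-pair fixtures with planted overlaps.

Every pipeline stage can be exercised without external data: the generator
produces two Markush patents whose enumerated claim languages intersect in
exactly a planted set of compounds, plus a code table sized to the
alphabet.  Two named presets rebuild the worked desk-scale examples — the
two-data-qubit comparison with marked sets {11, 00} vs {00}, and the
eight-data-qubit comparison whose overlap encodes to basis states 2 and
128.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import CodeTable, MarkushPatent, build_code_table

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "PRESETS"]

_ALPHABET = "CONSPFIB"  # single-character SMILES-like element symbols


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random planted-overlap fixture."""

    seed: int
    alphabet_size: int = 3
    max_len: int = 3
    claims_per_patent: int = 4
    planted_overlap: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.alphabet_size <= len(_ALPHABET):
            raise ValueError(f"alphabet_size must be in [1, {len(_ALPHABET)}]")
        if self.planted_overlap > self.claims_per_patent:
            raise ValueError("planted_overlap cannot exceed claims_per_patent")
        if self.max_len < 1 or self.claims_per_patent < 1:
            raise ValueError("max_len and claims_per_patent must be >= 1")


@dataclass(frozen=True)
class Fixture:
    """A generated comparison problem."""

    patent_m: MarkushPatent
    patent_k: MarkushPatent
    table: CodeTable
    expected_overlap: frozenset[str]  # closed under alternative notations
    name: str = "random"


def _two_qubit_fixture() -> Fixture:
    # Two-data-qubit case: one patent marks the codes 11 and 00, the other
    # only 00.  With a 2-bit table over three symbols, the code 11 is the
    # padding symbol, i.e. the empty compound, and 00 is the first symbol.
    table = build_code_table(["A", "B", "C"])
    patent_m = MarkushPatent(core="{R1}", rules={"R1": ["A", ""]})
    patent_k = MarkushPatent(core="A")
    return Fixture(patent_m=patent_m, patent_k=patent_k, table=table,
                   expected_overlap=frozenset({"A"}), name="two-qubit")


def _chain_overlap_fixture() -> Fixture:
    # Eight-data-qubit case: patent 1 claims CC{R1} with two R1 members,
    # patent 2 claims O{R2} with three R2 members; the overlap is the single
    # molecule written CCCO / OCCC, encoding to basis states 2 and 128.
    table = build_code_table(["C", "O"], assignments={"C": "00", "O": "10"})
    patent_m = MarkushPatent(core="CC{R1}", rules={"R1": ["CO", "C"]})
    patent_k = MarkushPatent(core="O{R2}", rules={"R2": ["CCC", "CC", "C"]})
    return Fixture(patent_m=patent_m, patent_k=patent_k, table=table,
                   expected_overlap=frozenset({"CCCO", "OCCC"}), name="chain-overlap")


PRESETS = {"two-qubit": _two_qubit_fixture, "chain-overlap": _chain_overlap_fixture}


def generate_fixture(spec: FixtureSpec | str) -> Fixture:
    """Build a fixture: either a named preset or a seeded random pair.

    Random pairs: claim strings are unbranched chains over the alphabet;
    the two claim sets share exactly ``planted_overlap`` molecules, and all
    non-planted claims are distinct even up to string reversal so that
    alternative-notation expansion cannot create accidental overlaps.  The
    expected overlap is reported closed under reversal (both notations of a
    planted molecule are claimed-by-both).
    """
    if isinstance(spec, str):
        try:
            return PRESETS[spec]()
        except KeyError:
            raise ValueError(f"unknown preset {spec!r}; choose from {sorted(PRESETS)}") from None

    alphabet = list(_ALPHABET[: spec.alphabet_size])
    rng = np.random.default_rng(spec.seed)

    # sample distinct reversal-equivalence classes of chains
    n_classes_needed = 2 * spec.claims_per_patent - spec.planted_overlap
    capacity = sum(len(alphabet) ** l for l in range(1, spec.max_len + 1))
    if n_classes_needed > capacity // 2 + 1:
        raise ValueError("spec infeasible: not enough distinct chains for the alphabet")
    chosen: list[str] = []
    seen_classes: set[frozenset[str]] = set()
    while len(chosen) < n_classes_needed:
        length = int(rng.integers(1, spec.max_len + 1))
        s = "".join(rng.choice(alphabet, size=length))
        cls = frozenset({s, s[::-1]})
        if cls in seen_classes:
            continue
        seen_classes.add(cls)
        chosen.append(s)

    planted = chosen[: spec.planted_overlap]
    rest = chosen[spec.planted_overlap :]
    only_m = rest[: spec.claims_per_patent - spec.planted_overlap]
    only_k = rest[spec.claims_per_patent - spec.planted_overlap :]

    patent_m = MarkushPatent(core="{R1}", rules={"R1": planted + only_m})
    patent_k = MarkushPatent(core="{R1}", rules={"R1": planted + only_k})
    table = build_code_table(alphabet)
    expected = frozenset(s for p in planted for s in (p, p[::-1]))
    return Fixture(patent_m=patent_m, patent_k=patent_k, table=table,
                   expected_overlap=expected)
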