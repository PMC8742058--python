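"""SMILES <-> basis-state encoding and Markush claim grammars.

A Markush structure claims a family of compounds: an invariant core plus
variable R groups, each R group defined by production rules that may
reference further R groups.  As long as the reference graph is acyclic the
claimed language is finite and can be enumerated or counted exactly.

To place a compound on a quantum register, every SMILES symbol is mapped to
a fixed-width bitstring by a code table that reserves one extra code for an
"empty" padding symbol; shorter strings are padded so that every compound
occupies the same number of symbols.  The concatenated bitstring, read
left-to-right as a big-endian integer, is the index of the computational
basis state representing the compound.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import yaml

__all__ = [
    "CodeTable",
    "MarkushPatent",
    "EncodedCompound",
    "CyclicGrammarError",
    "build_code_table",
    "required_qubits",
    "tokenize",
    "encode_smiles",
    "decode_bitstring",
    "enumerate_claims",
    "count_claims",
    "alternative_notations",
    "load_patent",
    "load_smiles_list",
    "load_code_table",
    "save_code_table",
]


class CyclicGrammarError(ValueError):
    """Raised when the R-group reference graph contains a cycle."""


# ---------------------------------------------------------------------------
# code table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodeTable:
    """Bijection between SMILES symbols and fixed-width bitstrings.

    One code of the space is reserved for the empty/padding symbol and maps
    to no chemical symbol.
    """

    entries: Mapping[str, str]
    bits_per_symbol: int
    empty_code: str

    def __post_init__(self) -> None:
        codes = list(self.entries.values()) + [self.empty_code]
        for code in codes:
            if len(code) != self.bits_per_symbol or set(code) - {"0", "1"}:
                raise ValueError(f"code {code!r} is not {self.bits_per_symbol} bits wide")
        if len(set(codes)) != len(codes):
            raise ValueError("codes are not distinct")
        if len(self.entries) > 2**self.bits_per_symbol - 1:
            raise ValueError("too many symbols for the code width")

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def code_of(self, symbol: str) -> str:
        try:
            return self.entries[symbol]
        except KeyError:
            raise KeyError(f"symbol {symbol!r} is not in the code table") from None

    def symbol_of(self, code: str) -> str:
        inv = {c: s for s, c in self.entries.items()}
        try:
            return inv[code]
        except KeyError:
            raise KeyError(f"code {code!r} maps to no symbol") from None


def build_code_table(
    symbols: Sequence[str],
    assignments: Mapping[str, str] | None = None,
) -> CodeTable:
    """Build a code table for the given symbols.

    The width is ``ceil(log2(len(symbols)+1))`` so that one all-ones code is
    left over for the padding symbol.  Codes are assigned in input order
    starting at 0; ``assignments`` may pin specific symbols to specific
    codes (e.g. pinning ``C -> 00`` and ``O -> 10`` to match an existing table).
    """
    if not symbols:
        raise ValueError("symbols must be non-empty")
    seen: set[str] = set()
    for s in symbols:
        if s in seen:
            raise ValueError(f"duplicate symbol {s!r}")
        seen.add(s)
    bits = max(1, math.ceil(math.log2(len(symbols) + 1)))
    empty = "1" * bits
    entries: dict[str, str] = {}
    taken = {empty}
    assignments = dict(assignments or {})
    for sym, code in assignments.items():
        if sym not in seen:
            raise ValueError(f"assignment for unknown symbol {sym!r}")
        if len(code) != bits:
            raise ValueError(f"assigned code {code!r} is not {bits} bits wide")
        if code in taken:
            raise ValueError(f"assigned code {code!r} collides")
        entries[sym] = code
        taken.add(code)
    free = (format(i, f"0{bits}b") for i in range(2**bits))
    for sym in symbols:
        if sym in entries:
            continue
        code = next(c for c in free if c not in taken)
        entries[sym] = code
        taken.add(code)
    # preserve input order
    entries = {s: entries[s] for s in symbols}
    return CodeTable(entries=entries, bits_per_symbol=bits, empty_code=empty)


def required_qubits(n_symbols_in_string: int, n_distinct_symbols: int) -> int:
    """Data qubits needed for a string of given length over a symbol set.

    The padding symbol counts as one of the distinct symbols: a 3-character
    string over 4 symbols (3 chemical + empty) needs ``3 * ceil(log2 4) = 6``
    qubits.
    """
    if n_symbols_in_string < 1 or n_distinct_symbols < 1:
        raise ValueError("both arguments must be >= 1")
    return n_symbols_in_string * max(1, math.ceil(math.log2(n_distinct_symbols)))


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EncodedCompound:
    """A SMILES string together with its bitstring and basis-state index."""

    smiles: str
    bitstring: str
    basis_index: int


def tokenize(smiles: str, tokens: Sequence[str] | None = None) -> list[str]:
    """Split a SMILES string into symbols.

    Single characters by default; when ``tokens`` is given, multi-character
    tokens (e.g. ``Cl``) are matched greedily, longest first.
    """
    if tokens is None:
        return list(smiles)
    ordered = sorted(tokens, key=len, reverse=True)
    out: list[str] = []
    i = 0
    while i < len(smiles):
        for t in ordered:
            if smiles.startswith(t, i):
                out.append(t)
                i += len(t)
                break
        else:
            raise ValueError(f"cannot tokenize {smiles!r} at position {i}")
    return out


def encode_smiles(
    smiles: str,
    table: CodeTable,
    max_len: int,
    tokens: Sequence[str] | None = None,
) -> EncodedCompound:
    """Encode a SMILES string as a padded bitstring and basis index.

    Per-symbol codes are concatenated and the empty code is appended until
    the string occupies ``max_len`` symbols; the bitstring read left-to-right
    is the big-endian binary of the basis index.
    """
    syms = tokenize(smiles, tokens)
    if len(syms) > max_len:
        raise ValueError(f"{smiles!r} has {len(syms)} symbols, exceeding max_len={max_len}")
    parts = [table.code_of(s) for s in syms]
    parts += [table.empty_code] * (max_len - len(syms))
    bits = "".join(parts)
    return EncodedCompound(smiles=smiles, bitstring=bits, basis_index=int(bits, 2))


def decode_bitstring(bits: str, table: CodeTable) -> str:
    """Inverse of :func:`encode_smiles`: strip padding, map codes to symbols.

    Padding codes must form a contiguous suffix; a chemical code after a
    padding code, or an unassigned code, is rejected.
    """
    w = table.bits_per_symbol
    if len(bits) % w:
        raise ValueError(f"bit width {len(bits)} not divisible by {w}")
    chunks = [bits[i : i + w] for i in range(0, len(bits), w)]
    out: list[str] = []
    in_padding = False
    for chunk in chunks:
        if chunk == table.empty_code:
            in_padding = True
            continue
        if in_padding:
            raise ValueError(f"chemical code {chunk!r} after padding in {bits!r}")
        out.append(table.symbol_of(chunk))
    return "".join(out)


# ---------------------------------------------------------------------------
# Markush grammars
# ---------------------------------------------------------------------------

_PLACEHOLDER = re.compile(r"\{([^{}]+)\}")


def _split_template(template: str) -> list[tuple[str, str]]:
    """Split a template into ('lit', text) and ('ref', name) parts."""
    parts: list[tuple[str, str]] = []
    pos = 0
    for m in _PLACEHOLDER.finditer(template):
        if m.start() > pos:
            parts.append(("lit", template[pos : m.start()]))
        parts.append(("ref", m.group(1)))
        pos = m.end()
    if pos < len(template):
        parts.append(("lit", template[pos:]))
    return parts


@dataclass(frozen=True)
class MarkushPatent:
    """A patent claim: core template plus R-group production rules.

    Templates reference R groups as ``{R1}``; ``terminals`` holds the leaf
    variation symbol(s) (conventionally ``R``) with their concrete SMILES
    fragment choices.  The reference graph must be acyclic, so the claimed
    language is finite.
    """

    core: str
    rules: Mapping[str, Sequence[str]] = field(default_factory=dict)
    terminals: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dup = set(self.rules) & set(self.terminals)
        if dup:
            raise ValueError(f"names defined both as rule and terminal: {sorted(dup)}")
        for name, prods in self.rules.items():
            if not prods:
                raise ValueError(f"R group {name!r} has no productions")
        for name, choices in self.terminals.items():
            if not choices:
                raise ValueError(f"terminal {name!r} has no choices")
        self._check_refs_and_cycles()

    def _refs_of(self, template: str) -> list[str]:
        return [name for kind, name in _split_template(template) if kind == "ref"]

    def _check_refs_and_cycles(self) -> None:
        defined = set(self.rules) | set(self.terminals)
        templates = [self.core]
        for prods in self.rules.values():
            templates.extend(prods)
        for t in templates:
            for ref in self._refs_of(t):
                if ref not in defined:
                    raise ValueError(f"undefined R group {ref!r} referenced in {t!r}")
        # DFS cycle check over rule names only (terminals are leaves)
        WHITE, GREY, BLACK = 0, 1, 2
        color = {name: WHITE for name in self.rules}
        stack: list[str] = []

        def visit(name: str) -> None:
            color[name] = GREY
            stack.append(name)
            for prod in self.rules[name]:
                for ref in self._refs_of(prod):
                    if ref in self.terminals:
                        continue
                    if color[ref] == GREY:
                        cycle = stack[stack.index(ref) :] + [ref]
                        raise CyclicGrammarError(
                            "cyclic R-group references: " + " -> ".join(cycle)
                        )
                    if color[ref] == WHITE:
                        visit(ref)
            stack.pop()
            color[name] = BLACK

        for name in self.rules:
            if color[name] == WHITE:
                visit(name)


def _expansions(patent: MarkushPatent, name: str, memo: dict[str, list[str]]) -> list[str]:
    if name in patent.terminals:
        return list(patent.terminals[name])
    if name not in memo:
        out: list[str] = []
        for prod in patent.rules[name]:
            out.extend(_expand_template(patent, prod, memo))
        memo[name] = out
    return memo[name]


def _expand_template(patent: MarkushPatent, template: str, memo: dict[str, list[str]]) -> list[str]:
    results = [""]
    for kind, val in _split_template(template):
        if kind == "lit":
            results = [r + val for r in results]
        else:
            options = _expansions(patent, val, memo)
            results = [r + o for r in results for o in options]
    return results


def enumerate_claims(patent: MarkushPatent, limit: int | None = None) -> list[str]:
    """Enumerate the claimed SMILES language, depth-first, deduplicated.

    Productions are expanded in the order given, later positions varying
    fastest; duplicate strings arising from different derivations are kept
    once.  ``limit`` truncates the output.
    """
    if limit is not None and limit < 1:
        raise ValueError("limit must be >= 1")
    seen: set[str] = set()
    out: list[str] = []
    for s in _expand_template(patent, patent.core, {}):
        if s not in seen:
            seen.add(s)
            out.append(s)
            if limit is not None and len(out) >= limit:
                break
    return out


def count_claims(patent: MarkushPatent) -> int:
    """Count derivations by dynamic programming over the R-group DAG.

    Equals ``len(enumerate_claims(patent))`` whenever no two derivations
    produce the same string (the DP counts derivations, not distinct
    strings).
    """
    memo: dict[str, int] = {}

    def count_name(name: str) -> int:
        if name in patent.terminals:
            return len(patent.terminals[name])
        if name not in memo:
            memo[name] = sum(count_template(p) for p in patent.rules[name])
        return memo[name]

    def count_template(template: str) -> int:
        total = 1
        for kind, val in _split_template(template):
            if kind == "ref":
                total *= count_name(val)
        return total

    return count_template(patent.core)


# ---------------------------------------------------------------------------
# alternative notations
# ---------------------------------------------------------------------------

_BRANCH_CHARS = set("()[]%0123456789")


def alternative_notations(
    smiles: str,
    tokens: Sequence[str] | None = None,
    expander: Callable[[str], set[str]] | None = None,
) -> set[str]:
    """Equivalent linear SMILES notations of an unbranched chain.

    One molecule admits many SMILES strings; for an unbranched chain the
    built-in generator returns the string and its reversal (multi-character
    tokens kept intact).  Branched or ring inputs are rejected unless a
    pluggable ``expander`` is supplied.
    """
    if expander is not None:
        return set(expander(smiles))
    if set(smiles) & _BRANCH_CHARS:
        raise ValueError(
            f"{smiles!r} contains branches or ring closures; general SMILES "
            "enumeration is not built in — pass expander= to plug one in"
        )
    syms = tokenize(smiles, tokens)
    return {smiles, "".join(reversed(syms))}


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def load_patent(path: str) -> MarkushPatent:
    """Read a patent spec file (YAML: core / rules / terminals)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "core" not in doc:
        raise ValueError(f"{path}: expected a mapping with a 'core' key")
    return MarkushPatent(
        core=str(doc["core"]),
        rules={str(k): [str(p) for p in v] for k, v in (doc.get("rules") or {}).items()},
        terminals={str(k): [str(p) for p in v] for k, v in (doc.get("terminals") or {}).items()},
    )


def save_patent(patent: MarkushPatent, path: str) -> None:
    doc = {
        "core": patent.core,
        "rules": {k: list(v) for k, v in patent.rules.items()},
        "terminals": {k: list(v) for k, v in patent.terminals.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_smiles_list(path: str) -> list[str]:
    """Read a plain-text SMILES list: one compound per line, '#' comments."""
    out: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def load_code_table(path: str) -> CodeTable:
    """Read a two-column ``symbol<TAB>code`` table; the ``EMPTY`` row names
    the padding code."""
    entries: dict[str, str] = {}
    empty: str | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            sym, code = line.split("\t")
            if sym == "EMPTY":
                empty = code
            else:
                entries[sym] = code
    if empty is None:
        raise ValueError(f"{path}: missing EMPTY row")
    return CodeTable(entries=entries, bits_per_symbol=len(empty), empty_code=empty)


def save_code_table(table: CodeTable, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sym, code in table.entries.items():
            fh.write(f"{sym}\t{code}\n")
        fh.write(f"EMPTY\t{table.empty_code}\n")
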