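"""Boolean minimization of marked-set oracles.

A marked set of bitstrings is a Boolean function in disjunctive normal
form: one product term per marked string.  Minimizing the function (prime
implicants, then factoring out literals shared by every term) often yields
a far smaller recognizer, e.g. three 4-variable minterms collapsing to
``~A & ~C & (~B | ~D)``.  The factored form maps onto a circuit with one
scratch ancilla per OR clause (OR realized through De Morgan as the
negation of an AND), all scratch ancillas uncomputed at the end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sympy import symbols as sym_symbols
from sympy.logic import SOPform
from sympy.logic.boolalg import And, Not, Or, BooleanTrue, BooleanFalse
from sympy import Symbol

from .circuit import Circuit, Statevector, simulate

__all__ = [
    "Literal",
    "BooleanExpr",
    "dnf_from_marked",
    "simplify",
    "circuit_from_expr",
    "oracles_equivalent",
    "parse_expr",
    "format_expr",
]

Literal = tuple[str, bool]  # (variable name, negated?)


@dataclass(frozen=True)
class BooleanExpr:
    """A Boolean function over named variables.

    Exactly one of two shapes:

    * sum-of-products: ``terms`` is a tuple of product terms, each a tuple
      of literals (empty ``terms`` is the constant False);
    * AND of clauses: ``clauses`` is a tuple of OR-clauses, each a tuple of
      literals (empty ``clauses`` is the constant True).
    """

    variables: tuple[str, ...]
    terms: tuple[tuple[Literal, ...], ...] | None = None
    clauses: tuple[tuple[Literal, ...], ...] | None = None

    def __post_init__(self) -> None:
        if (self.terms is None) == (self.clauses is None):
            raise ValueError("exactly one of terms/clauses must be given")
        declared = set(self.variables)
        for group in self.terms if self.terms is not None else self.clauses:
            for name, _neg in group:
                if name not in declared:
                    raise ValueError(f"undeclared variable {name!r}")

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, assignment: dict[str, bool]) -> bool:
        def lit(l: Literal) -> bool:
            name, neg = l
            v = assignment[name]
            return (not v) if neg else v

        if self.terms is not None:
            return any(all(lit(l) for l in t) for t in self.terms)
        return all(any(lit(l) for l in cl) for cl in self.clauses)

    def satisfying_set(self) -> frozenset[str]:
        """All satisfying assignments as bitstrings in variable order."""
        out = []
        for values in itertools.product([0, 1], repeat=len(self.variables)):
            assignment = dict(zip(self.variables, map(bool, values)))
            if self.evaluate(assignment):
                out.append("".join(str(v) for v in values))
        return frozenset(out)

    def literal_count(self) -> int:
        groups = self.terms if self.terms is not None else self.clauses
        return sum(len(g) for g in groups)


def dnf_from_marked(marked: set[str] | frozenset[str],
                    variables: Sequence[str]) -> BooleanExpr:
    """One product term per marked string; literal polarity from the bit."""
    variables = tuple(variables)
    terms = []
    for bits in sorted(marked):
        if len(bits) != len(variables):
            raise ValueError(
                f"bitstring {bits!r} does not match {len(variables)} variables"
            )
        terms.append(tuple((v, b == "0") for v, b in zip(variables, bits)))
    return BooleanExpr(variables=variables, terms=tuple(terms))


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------


def _sort_lits(lits, order: dict[str, int]):
    return tuple(sorted(lits, key=lambda l: order[l[0]]))


def _sympy_to_terms(expr, order: dict[str, int]) -> tuple[tuple[Literal, ...], ...]:
    if isinstance(expr, BooleanFalse):
        return ()
    if isinstance(expr, BooleanTrue):
        return ((),)
    prods = expr.args if isinstance(expr, Or) else (expr,)
    terms = []
    for p in prods:
        lits = p.args if isinstance(p, And) else (p,)
        term = []
        for l in lits:
            if isinstance(l, Not):
                term.append((str(l.args[0]), True))
            elif isinstance(l, Symbol):
                term.append((str(l), False))
            else:
                raise ValueError(f"unexpected sympy literal {l!r}")
        terms.append(_sort_lits(term, order))
    return tuple(sorted(terms))


def simplify(expr: BooleanExpr) -> BooleanExpr:
    """Minimize an expression; output is logically equivalent and no larger.

    Prime implicants are computed (Quine–McCluskey via sympy's SOPform),
    then literals common to every term are factored out; when each residual
    term is a single literal the result is the AND-of-clauses form, which
    maps directly onto a compressed circuit.  Ties are broken by variable
    order so the output is deterministic.
    """
    order = {v: i for i, v in enumerate(expr.variables)}
    sat = sorted(int(b, 2) for b in expr.satisfying_set())
    n = len(expr.variables)
    if not sat:
        return BooleanExpr(variables=expr.variables, terms=())
    if len(sat) == 2**n:
        return BooleanExpr(variables=expr.variables, clauses=())
    syms = sym_symbols(" ".join(expr.variables)) if n > 1 else (Symbol(expr.variables[0]),)
    if n > 1:
        syms = list(syms)
    minterms = [[(m >> (n - 1 - i)) & 1 for i in range(n)] for m in sat]
    sop = SOPform(syms, minterms)
    terms = _sympy_to_terms(sop, order)
    result = _factor(expr.variables, terms, order)
    if result.literal_count() > expr.literal_count():
        result = expr  # never grow
    assert result.satisfying_set() == expr.satisfying_set()
    return result


def _factor(variables: tuple[str, ...],
            terms: tuple[tuple[Literal, ...], ...],
            order: dict[str, int]) -> BooleanExpr:
    """Greedy shared-literal factoring of a minimal SOP."""
    if len(terms) == 1:
        # a single product: AND of single-literal clauses
        return BooleanExpr(variables=variables,
                           clauses=tuple((l,) for l in terms[0]))
    common = set(terms[0])
    for t in terms[1:]:
        common &= set(t)
    residual = [tuple(l for l in t if l not in common) for t in terms]
    if any(len(r) > 1 for r in residual):
        return BooleanExpr(variables=variables, terms=terms)
    if any(len(r) == 0 for r in residual):
        # some term reduces to the common part alone: OR clause is true
        clauses = tuple((l,) for l in _sort_lits(common, order))
    else:
        or_clause = _sort_lits((r[0] for r in residual), order)
        clauses = tuple((l,) for l in _sort_lits(common, order)) + (or_clause,)
    return BooleanExpr(variables=variables, clauses=clauses)


# ---------------------------------------------------------------------------
# circuits
# ---------------------------------------------------------------------------


def _terms_disjoint(terms) -> bool:
    for a, b in itertools.combinations(terms, 2):
        da, db = dict(a), dict(b)
        if not any(name in db and db[name] != neg for name, neg in da.items()):
            return False
    return True


def circuit_from_expr(expr: BooleanExpr, target_ancilla: int) -> Circuit:
    """Compile an expression into an indicator circuit onto ``target_ancilla``.

    AND-of-clauses form: single-literal clauses become (possibly X-conjugated)
    controls of one final MCX; every OR clause gets a scratch ancilla holding
    its value via De Morgan (MCX of the negated literals, then X), and all
    scratch ancillas are uncomputed after the final MCX.  A sum of pairwise
    disjoint products is compiled as one marking block per term; overlapping
    products get one scratch ancilla each, OR-combined into the target
    through De Morgan and then uncomputed.
    """
    n_data = len(expr.variables)
    if target_ancilla < n_data:
        raise ValueError("target_ancilla must lie beyond the data register")
    qubit = {v: i for i, v in enumerate(expr.variables)}

    if expr.terms is not None:
        if _terms_disjoint(expr.terms):
            c = Circuit(n_data, target_ancilla - n_data + 1)
            for term in expr.terms:
                if not term:  # constant-true term
                    c.add("x", target_ancilla)
                    continue
                flips = [qubit[name] for name, neg in term if neg]
                for q in flips:
                    c.add("x", q)
                controls = [qubit[name] for name, _ in term]
                c.add("mcx", *controls, target_ancilla)
                for q in flips:
                    c.add("x", q)
            return c
        # overlapping products: one scratch per term, OR via De Morgan
        n_terms = len(expr.terms)
        scratch = list(range(target_ancilla + 1, target_ancilla + 1 + n_terms))
        c = Circuit(n_data, target_ancilla - n_data + 1 + n_terms)
        forward: list = []
        for term, s in zip(expr.terms, scratch):
            if not term:
                forward.append(("x", (s,)))
                continue
            flips = [qubit[name] for name, neg in term if neg]
            for q in flips:
                forward.append(("x", (q,)))
            forward.append(("mcx", tuple(qubit[name] for name, _ in term) + (s,)))
            for q in flips:
                forward.append(("x", (q,)))
        for kind, qs in forward:
            c.add(kind, *qs)
        for s in scratch:  # target <- NOT(AND(NOT s_i)) = OR(s_i)
            c.add("x", s)
        c.add("mcx", *scratch, target_ancilla)
        c.add("x", target_ancilla)
        for s in scratch:
            c.add("x", s)
        for kind, qs in reversed(forward):
            c.add(kind, *qs)
        return c

    if not expr.clauses:  # constant true
        c = Circuit(n_data, target_ancilla - n_data + 1)
        c.add("x", target_ancilla)
        return c

    singles = [cl[0] for cl in expr.clauses if len(cl) == 1]
    ors = [cl for cl in expr.clauses if len(cl) > 1]
    n_scratch = len(ors)
    scratch = list(range(target_ancilla + 1, target_ancilla + 1 + n_scratch))
    c = Circuit(n_data, target_ancilla - n_data + 1 + n_scratch)

    def compute_or(clause, s: int, gates_out: list) -> None:
        # scratch <- OR(lits) = NOT(AND(neg lits)); X-conjugate where the
        # negated literal requires the variable to be 0
        flips = [qubit[name] for name, neg in clause if not neg]
        for q in flips:
            gates_out.append(("x", (q,)))
        gates_out.append(("mcx", tuple(qubit[name] for name, _ in clause) + (s,)))
        for q in flips:
            gates_out.append(("x", (q,)))
        gates_out.append(("x", (s,)))

    forward: list = []
    for clause, s in zip(ors, scratch):
        compute_or(clause, s, forward)
    for kind, qs in forward:
        c.add(kind, *qs)

    flips = [qubit[name] for name, neg in singles if neg]
    for q in flips:
        c.add("x", q)
    controls = [qubit[name] for name, _ in singles] + scratch
    c.add("mcx", *controls, target_ancilla)
    for q in flips:
        c.add("x", q)

    for kind, qs in reversed(forward):  # all blocks are self-inverse
        c.add(kind, *qs)
    return c


def oracles_equivalent(a: Circuit, b: Circuit, n_data: int,
                       target_a: int | None = None,
                       target_b: int | None = None) -> bool:
    """Exhaustively compare two indicator circuits on the data register.

    For every data basis state (ancillas in |0>), both circuits must map it
    to a +-phase basis state with identical data bits, identical indicator
    bit on their target ancilla, all other ancillas back at |0>, and equal
    phase.  Limited to ``n_data <= 10``.
    """
    if n_data > 10:
        raise ValueError("exhaustive equivalence check limited to n_data <= 10")
    target_a = n_data if target_a is None else target_a
    target_b = n_data if target_b is None else target_b

    def signature(circ: Circuit, target: int, x: int):
        init = Statevector.basis(x, circ.n_data, circ.n_ancilla)
        final = simulate(circ, init)
        amps = final.amplitudes
        idx = int(np.argmax(np.abs(amps)))
        if abs(abs(amps[idx]) - 1.0) > 1e-9:
            return None  # not a basis state: no classical signature
        n = circ.n_qubits
        bits = format(idx, f"0{n}b")
        data = bits[:n_data]
        indicator = bits[target]
        others = bits[n_data:target] + bits[target + 1:]
        phase = complex(amps[idx])
        return (data, indicator, others == "0" * len(others), round(phase.real, 9),
                round(phase.imag, 9))

    for x in range(2**n_data):
        sa = signature(a, target_a, x)
        sb = signature(b, target_b, x)
        if sa is None or sb is None or sa != sb:
            return False
    return True


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------


def format_expr(expr: BooleanExpr) -> str:
    """Print in the ``~A & ~C & (~B | ~D)`` dialect."""

    def lit(l: Literal) -> str:
        name, neg = l
        return ("~" if neg else "") + name

    if expr.clauses is not None:
        if not expr.clauses:
            return "1"
        parts = []
        for cl in expr.clauses:
            if len(cl) == 1:
                parts.append(lit(cl[0]))
            else:
                parts.append("(" + " | ".join(lit(l) for l in cl) + ")")
        return " & ".join(parts)
    if not expr.terms:
        return "0"
    parts = []
    for t in expr.terms:
        body = " & ".join(lit(l) for l in t) if t else "1"
        parts.append("(" + body + ")" if len(expr.terms) > 1 else body)
    return " | ".join(parts)


class _Parser:
    _TOKEN = None

    def __init__(self, text: str):
        import re

        self.tokens = re.findall(r"~|\&|\||\(|\)|\w+|1|0", text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect(self, tok: str):
        got = self.take()
        if got != tok:
            raise ValueError(f"expected {tok!r}, got {got!r}")

    # precedence: | lowest, & higher, ~ binds to a variable
    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise ValueError(f"trailing input at {self.peek()!r}")
        return node

    def parse_or(self):
        kids = [self.parse_and()]
        while self.peek() == "|":
            self.take()
            kids.append(self.parse_and())
        return kids[0] if len(kids) == 1 else ("or", kids)

    def parse_and(self):
        kids = [self.parse_atom()]
        while self.peek() == "&":
            self.take()
            kids.append(self.parse_atom())
        return kids[0] if len(kids) == 1 else ("and", kids)

    def parse_atom(self):
        tok = self.peek()
        if tok == "(":
            self.take()
            node = self.parse_or()
            self.expect(")")
            return node
        if tok == "~":
            self.take()
            name = self.take()
            return ("lit", name, True)
        if tok in ("0", "1"):
            self.take()
            return ("const", tok == "1")
        name = self.take()
        if name is None:
            raise ValueError("unexpected end of input")
        return ("lit", name, False)


def parse_expr(text: str, variables: Sequence[str] | None = None) -> BooleanExpr:
    """Parse the ``~A & ~C & (~B | ~D)`` dialect back into a BooleanExpr."""
    ast = _Parser(text).parse()

    def collect_vars(node, acc: list[str]):
        tag = node[0]
        if tag == "lit" and node[1] not in acc:
            acc.append(node[1])
        elif tag in ("and", "or"):
            for k in node[1]:
                collect_vars(k, acc)

    found: list[str] = []
    collect_vars(ast, found)
    variables = tuple(variables) if variables is not None else tuple(sorted(found))

    def as_literal(node) -> Literal | None:
        return (node[1], node[2]) if node[0] == "lit" else None

    def as_or_of_literals(node):
        if node[0] == "lit":
            return (as_literal(node),)
        if node[0] == "or":
            lits = [as_literal(k) for k in node[1]]
            return tuple(lits) if all(l is not None for l in lits) else None
        return None

    def as_and_of_literals(node):
        if node[0] == "lit":
            return (as_literal(node),)
        if node[0] == "and":
            lits = [as_literal(k) for k in node[1]]
            return tuple(lits) if all(l is not None for l in lits) else None
        return None

    if ast[0] == "const":
        return (BooleanExpr(variables=variables, clauses=())
                if ast[1] else BooleanExpr(variables=variables, terms=()))
    if ast[0] == "or":
        terms = []
        for kid in ast[1]:
            t = as_and_of_literals(kid)
            if t is None:
                raise ValueError("expression is neither AND-of-clauses nor a sum of products")
            terms.append(t)
        return BooleanExpr(variables=variables, terms=tuple(terms))
    # top-level AND (or a single atom): clause form
    kids = ast[1] if ast[0] == "and" else [ast]
    clauses = []
    for kid in kids:
        cl = as_or_of_literals(kid)
        if cl is None:
            raise ValueError("unsupported nesting in expression")
        clauses.append(cl)
    return BooleanExpr(variables=variables, clauses=tuple(clauses))
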