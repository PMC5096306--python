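"""Closed boolean mini-language over whole-molecule properties.

Some categories are defined not by a substructure but by counting rules over
the molecular formula and ring census — the classic example is the alkane,
an acyclic hydrocarbon of formula CnH2n+2:

    RingCount() = 0 and AtomCount(C) > 0
        and AtomCount(C) + AtomCount(H) = TotalAtomCount()
        and AtomCount(H) = 2 * AtomCount(C) + 2

The grammar is closed (no attribute access, no calls beyond the fixed
property vocabulary), so rule files can never execute arbitrary code.
Property terms: ``AtomCount(<element>)``, ``TotalAtomCount()``,
``RingCount()``, ``AromaticRingCount()`` and ``MolecularFormula(<formula>)``;
arithmetic is ``+`` and ``*`` with integer constants; comparisons are
``= > < >= <=`` (``!=`` is deliberately absent — negate with ``not``);
connectives are ``and``, ``or``, ``not``.  Hydrogen counts include implicit
hydrogens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol

__all__ = ["PredicateExpr", "PredicateError", "parse_predicate"]


class PredicateError(ValueError):
    """Malformed predicate expression text."""


class MoleculeProperties(Protocol):
    """What an expression needs from a molecule (duck-typed)."""

    formula: dict[str, int]
    ring_count: int
    aromatic_ring_count: int


# -- AST -----------------------------------------------------------------------


class PredicateExpr:
    """Base class for all predicate AST nodes."""

    def evaluate(self, mol: MoleculeProperties) -> bool:
        raise NotImplementedError

    def unparse(self) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.unparse()!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PredicateExpr) and self.unparse() == other.unparse()

    def __hash__(self) -> int:
        return hash(self.unparse())


class _Arith:
    def value(self, mol: MoleculeProperties) -> int:
        raise NotImplementedError

    def unparse(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True, eq=False, repr=False)
class Const(_Arith):
    n: int

    def value(self, mol: MoleculeProperties) -> int:
        return self.n

    def unparse(self) -> str:
        return str(self.n)


@dataclass(frozen=True, eq=False, repr=False)
class AtomCount(_Arith):
    element: str

    def value(self, mol: MoleculeProperties) -> int:
        return mol.formula.get(self.element, 0)

    def unparse(self) -> str:
        return f"AtomCount({self.element})"


@dataclass(frozen=True, eq=False, repr=False)
class TotalAtomCount(_Arith):
    def value(self, mol: MoleculeProperties) -> int:
        return sum(mol.formula.values())

    def unparse(self) -> str:
        return "TotalAtomCount()"


@dataclass(frozen=True, eq=False, repr=False)
class RingCount(_Arith):
    def value(self, mol: MoleculeProperties) -> int:
        return mol.ring_count

    def unparse(self) -> str:
        return "RingCount()"


@dataclass(frozen=True, eq=False, repr=False)
class AromaticRingCount(_Arith):
    def value(self, mol: MoleculeProperties) -> int:
        return mol.aromatic_ring_count

    def unparse(self) -> str:
        return "AromaticRingCount()"


@dataclass(frozen=True, eq=False, repr=False)
class BinOp(_Arith):
    op: str  # "+" or "*"
    left: _Arith
    right: _Arith

    def value(self, mol: MoleculeProperties) -> int:
        a, b = self.left.value(mol), self.right.value(mol)
        return a + b if self.op == "+" else a * b

    def unparse(self) -> str:
        return f"({self.left.unparse()} {self.op} {self.right.unparse()})"


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_to_counts(formula: str) -> dict[str, int]:
    """'C2H6O' -> {'C': 2, 'H': 6, 'O': 1} (Hill-agnostic, no parentheses)."""
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if not m or not m.group(1):
            raise PredicateError(f"malformed molecular formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    return counts


@dataclass(frozen=True, eq=False, repr=False)
class MolecularFormula(PredicateExpr):
    formula: str

    def evaluate(self, mol: MoleculeProperties) -> bool:
        want = formula_to_counts(self.formula)
        have = {el: n for el, n in mol.formula.items() if n}
        return want == have

    def unparse(self) -> str:
        return f"MolecularFormula({self.formula})"


@dataclass(frozen=True, eq=False, repr=False)
class Comparison(PredicateExpr):
    op: str  # one of = > < >= <=
    left: _Arith
    right: _Arith

    def evaluate(self, mol: MoleculeProperties) -> bool:
        a, b = self.left.value(mol), self.right.value(mol)
        return {
            "=": a == b,
            ">": a > b,
            "<": a < b,
            ">=": a >= b,
            "<=": a <= b,
        }[self.op]

    def unparse(self) -> str:
        return f"{self.left.unparse()} {self.op} {self.right.unparse()}"


@dataclass(frozen=True, eq=False, repr=False)
class And(PredicateExpr):
    terms: tuple[PredicateExpr, ...]

    def evaluate(self, mol: MoleculeProperties) -> bool:
        return all(t.evaluate(mol) for t in self.terms)

    def unparse(self) -> str:
        return "(" + " and ".join(t.unparse() for t in self.terms) + ")"


@dataclass(frozen=True, eq=False, repr=False)
class Or(PredicateExpr):
    terms: tuple[PredicateExpr, ...]

    def evaluate(self, mol: MoleculeProperties) -> bool:
        return any(t.evaluate(mol) for t in self.terms)

    def unparse(self) -> str:
        return "(" + " or ".join(t.unparse() for t in self.terms) + ")"


@dataclass(frozen=True, eq=False, repr=False)
class Not(PredicateExpr):
    term: PredicateExpr

    def evaluate(self, mol: MoleculeProperties) -> bool:
        return not self.term.evaluate(mol)

    def unparse(self) -> str:
        return f"not {self.term.unparse()}"


# -- parser --------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+)|(?P<name>[A-Za-z][A-Za-z0-9]*)|(?P<sym>>=|<=|==|[()+*=><]))"
)
_ELEMENT_RE = re.compile(r"^[A-Z][a-z]?$")


class _Parser:
    def __init__(self, text: str):
        self.tokens: list[str] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m or m.end() == pos:
                if text[pos:].strip():
                    raise PredicateError(
                        f"unexpected character {text[pos:].strip()[0]!r} in predicate"
                    )
                break
            self.tokens.append(m.group("num") or m.group("name") or m.group("sym"))
            pos = m.end()
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def pop(self, expect: str | None = None) -> str:
        tok = self.peek()
        if tok is None:
            raise PredicateError("unexpected end of predicate")
        if expect is not None and tok != expect:
            raise PredicateError(f"expected {expect!r}, found {tok!r}")
        self.i += 1
        return tok

    def parse(self) -> PredicateExpr:
        expr = self.or_expr()
        if self.peek() is not None:
            raise PredicateError(f"trailing tokens starting at {self.peek()!r}")
        return expr

    def or_expr(self) -> PredicateExpr:
        terms = [self.and_expr()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.pop()
            terms.append(self.and_expr())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def and_expr(self) -> PredicateExpr:
        terms = [self.not_expr()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.pop()
            terms.append(self.not_expr())
        return terms[0] if len(terms) == 1 else And(tuple(terms))

    def not_expr(self) -> PredicateExpr:
        if self.peek() is not None and self.peek().lower() == "not":
            self.pop()
            return Not(self.not_expr())
        return self.atom_expr()

    def atom_expr(self) -> PredicateExpr:
        # A parenthesis is ambiguous: it can open a boolean group or an
        # arithmetic group.  Try boolean first and fall back.
        if self.peek() == "(":
            saved = self.i
            self.pop()
            try:
                inner = self.or_expr()
                self.pop(")")
                return inner
            except PredicateError:
                self.i = saved
        if self.peek() is not None and self.peek() == "MolecularFormula":
            self.pop()
            self.pop("(")
            formula = self.pop()
            formula_to_counts(formula)  # validate eagerly
            self.pop(")")
            return MolecularFormula(formula)
        left = self.arith()
        op = self.pop()
        if op == "==":
            op = "="
        if op not in ("=", ">", "<", ">=", "<="):
            raise PredicateError(f"expected a comparison operator, found {op!r}")
        right = self.arith()
        return Comparison(op, left, right)

    def arith(self) -> _Arith:
        node = self.term()
        while self.peek() == "+":
            self.pop()
            node = BinOp("+", node, self.term())
        return node

    def term(self) -> _Arith:
        node = self.factor()
        while self.peek() == "*":
            self.pop()
            node = BinOp("*", node, self.factor())
        return node

    def factor(self) -> _Arith:
        tok = self.peek()
        if tok is None:
            raise PredicateError("unexpected end of predicate")
        if tok == "(":
            self.pop()
            node = self.arith()
            self.pop(")")
            return node
        if tok.isdigit():
            self.pop()
            return Const(int(tok))
        self.pop()
        if tok == "AtomCount":
            self.pop("(")
            element = self.pop()
            if not _ELEMENT_RE.match(element):
                raise PredicateError(f"invalid element symbol {element!r}")
            self.pop(")")
            return AtomCount(element)
        if tok in ("TotalAtomCount", "RingCount", "AromaticRingCount"):
            self.pop("(")
            self.pop(")")
            return {
                "TotalAtomCount": TotalAtomCount,
                "RingCount": RingCount,
                "AromaticRingCount": AromaticRingCount,
            }[tok]()
        raise PredicateError(f"unknown property term {tok!r}")


def parse_predicate(text: str) -> PredicateExpr:
    """Parse predicate text into an AST; raises :class:`PredicateError`."""
    return _Parser(text).parse()


def evaluate_predicate(expr: PredicateExpr, mol: MoleculeProperties) -> bool:
    """Total boolean evaluation of ``expr`` against a standardized molecule."""
    return expr.evaluate(mol)
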