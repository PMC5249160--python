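"""Boolean gene-protein-reaction (GPR) expressions.

A GPR associates a reaction with the boolean combination of genes whose
products can catalyse it: ``and`` encodes enzyme complexes (all subunits
required), ``or`` encodes isoenzymes (any one suffices).  The syntax follows
SBML-FBC gene-association strings: gene tokens combined with case-insensitive
``and`` / ``or`` and parentheses, with ``and`` binding tighter than ``or``.

Gene identifiers are opaque, case-sensitive strings; whitespace separates
tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Union

__all__ = [
    "GprExpression",
    "Gene",
    "BoolOp",
    "GprParseError",
    "parse_gpr",
    "serialize_gpr",
    "evaluate_gpr",
    "gene_is_associated",
    "gene_is_necessary",
    "isoenzyme_set",
    "or_to_and",
]


class GprParseError(ValueError):
    """Raised for malformed GPR strings (unbalanced parentheses, empty operands)."""


@dataclass(frozen=True)
class Gene:
    """Leaf node: a single gene identifier."""

    name: str

    def genes(self) -> frozenset[str]:
        return frozenset({self.name})


@dataclass(frozen=True)
class BoolOp:
    """Internal node: ``op`` is ``"and"`` or ``"or"`` over >= 2 children."""

    op: str  # "and" | "or"
    children: tuple["GprExpression", ...]

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown boolean operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("boolean node requires at least two children")

    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for child in self.children:
            out |= child.genes()
        return out


GprExpression = Union[Gene, BoolOp]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


class _Parser:
    """Recursive-descent parser; grammar:  or := and ('or' and)*;
    and := atom ('and' atom)*;  atom := gene | '(' or ')'."""

    def __init__(self, tokens: list[str], context: str):
        self.tokens = tokens
        self.pos = 0
        self.context = context

    def error(self, msg: str) -> GprParseError:
        return GprParseError(f"invalid GPR for {self.context}: {msg}")

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise self.error("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> GprExpression:
        expr = self.parse_or()
        if self.peek() is not None:
            raise self.error(f"unexpected token {self.peek()!r}")
        return expr

    def parse_or(self) -> GprExpression:
        children = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else BoolOp("or", tuple(children))

    def parse_and(self) -> GprExpression:
        children = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            children.append(self.parse_atom())
        return children[0] if len(children) == 1 else BoolOp("and", tuple(children))

    def parse_atom(self) -> GprExpression:
        tok = self.next()
        if tok == "(":
            expr = self.parse_or()
            if self.peek() != ")":
                raise self.error("unbalanced parentheses")
            self.next()
            return expr
        if tok == ")" or tok.lower() in ("and", "or"):
            raise self.error(f"empty operand near {tok!r}")
        return Gene(tok)


def parse_gpr(text: str, reaction: str = "<anonymous>") -> GprExpression:
    """Parse an SBML-FBC style gene-association string into an expression tree.

    ``and`` binds tighter than ``or`` when unparenthesized; operators are
    case-insensitive, gene identifiers case-sensitive.

    Raises
    ------
    GprParseError
        On empty input, unbalanced parentheses or missing operands; the
        message names ``reaction`` so model loading errors are traceable.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GprParseError(f"invalid GPR for {reaction}: empty expression")
    return _Parser(tokens, reaction).parse()


def serialize_gpr(expr: GprExpression) -> str:
    """Render with lowercase operators, fully parenthesized below the root."""
    if isinstance(expr, Gene):
        return expr.name
    parts = []
    for child in expr.children:
        s = serialize_gpr(child)
        if isinstance(child, BoolOp):
            s = f"({s})"
        parts.append(s)
    return f" {expr.op} ".join(parts)


def evaluate_gpr(expr: GprExpression, present: set[str] | frozenset[str]) -> bool:
    """Evaluate the GPR with exactly the genes in ``present`` available.

    Genes not listed are treated as deleted (false).  A reaction's enzyme can
    be formed iff this returns True.
    """
    if isinstance(expr, Gene):
        return expr.name in present
    if expr.op == "and":
        return all(evaluate_gpr(c, present) for c in expr.children)
    return any(evaluate_gpr(c, present) for c in expr.children)


def gene_is_associated(expr: GprExpression, gene: str) -> bool:
    """True iff ``gene`` appears anywhere in the expression tree."""
    return gene in expr.genes()


def gene_is_necessary(expr: GprExpression, gene: str) -> bool:
    """True iff deleting ``gene`` alone (all other genes present) disables the
    reaction — i.e. the gene is a necessary prerequisite for catalysis."""
    return not evaluate_gpr(expr, expr.genes() - {gene})


def isoenzyme_set(expr: GprExpression) -> frozenset[str]:
    """Genes individually sufficient to satisfy the GPR, when at least two are.

    A gene is individually sufficient if the expression evaluates true with
    only that gene present.  Two or more mutually substitutable genes form an
    isoenzyme set; a lone sufficient gene (e.g. a single-gene GPR, or the
    stand-alone arm of ``(a and b) or c``) does not, and the empty set is
    returned in that case.
    """
    sufficient = frozenset(
        g for g in expr.genes() if evaluate_gpr(expr, frozenset({g}))
    )
    return sufficient if len(sufficient) >= 2 else frozenset()


def or_to_and(expr: GprExpression) -> GprExpression:
    """Rewrite every OR node into an AND node (non-redundant isoenzymes).

    Under the rewritten rule, deleting any member of an isoenzyme set disables
    the reaction, instead of the remaining members providing full backup.  The
    rewrite is applied recursively and uniformly; it is idempotent and
    preserves the leaf gene set.
    """
    if isinstance(expr, Gene):
        return expr
    return BoolOp("and", tuple(or_to_and(c) for c in expr.children))


def iter_nodes(expr: GprExpression) -> Iterator[GprExpression]:
    """Depth-first iteration over all nodes of the tree."""
    yield expr
    if isinstance(expr, BoolOp):
        for child in expr.children:
            yield from iter_nodes(child)
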