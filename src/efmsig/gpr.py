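"""Gene-protein-reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers in which ``and``
encodes enzyme complexes (every subunit required) and ``or`` encodes
isozymes (any one suffices).  Rules are evaluated here over three-valued
gene states ordered -1 < 0 < +1 (lowly / normally / highly expressed, or
down / unchanged / up), with ``and`` as minimum and ``or`` as maximum --
the standard extension of boolean conjunction/disjunction to ordered
levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Union


class GPRParseError(ValueError):
    """Raised when a GPR string does not conform to the grammar."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class GeneRef:
    """Leaf node: a bare gene identifier."""

    gene: str


@dataclass(frozen=True)
class BoolOp:
    """Internal node: ``and`` / ``or`` over exactly two children."""

    op: str  # "and" | "or"
    left: "GPRRule"
    right: "GPRRule"


GPRRule = Union[GeneRef, BoolOp]

_KEYWORDS = {"and", "or"}


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            yield ("paren", c, i)
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        if word.lower() in _KEYWORDS:
            yield ("op", word.lower(), i)
        else:
            yield ("gene", word, i)
        i = j


class _Parser:
    # grammar: expr := term ('or' term)* ; term := factor ('and' factor)* ;
    # factor := gene | '(' expr ')'.  'and' binds tighter than 'or', both
    # left-associative.

    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of GPR expression", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> GPRRule:
        if not self.tokens:
            raise GPRParseError("empty GPR expression", 0)
        node = self.expr()
        tok = self.peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def expr(self) -> GPRRule:
        node = self.term()
        while (tok := self.peek()) is not None and tok[:2] == ("op", "or"):
            self.next()
            node = BoolOp("or", node, self.term())
        return node

    def term(self) -> GPRRule:
        node = self.factor()
        while (tok := self.peek()) is not None and tok[:2] == ("op", "and"):
            self.next()
            node = BoolOp("and", node, self.factor())
        return node

    def factor(self) -> GPRRule:
        kind, value, pos = self.next()
        if kind == "gene":
            return GeneRef(value)
        if (kind, value) == ("paren", "("):
            node = self.expr()
            kind2, value2, pos2 = self.next()
            if (kind2, value2) != ("paren", ")"):
                raise GPRParseError("expected ')'", pos2)
            return node
        raise GPRParseError(f"unexpected token {value!r}", pos)


def parse_gpr(text: str) -> GPRRule:
    """Parse a GPR string into an expression tree.

    ``and`` binds tighter than ``or``; both are left-associative and
    case-insensitive.  Raises :class:`GPRParseError` on malformed input,
    reporting the offending position.
    """
    return _Parser(text).parse()


def serialize_gpr(rule: GPRRule) -> str:
    """Render a rule back to text; ``parse_gpr`` inverts this exactly."""
    if isinstance(rule, GeneRef):
        return rule.gene
    parts = []
    for child in (rule.left, rule.right):
        s = serialize_gpr(child)
        # parenthesize an 'or' under an 'and', and any right-hand operand of
        # the same operator, so the left-associative parse reproduces the tree
        need = isinstance(child, BoolOp) and (
            (rule.op == "and" and child.op == "or") or child is rule.right
        )
        parts.append(f"({s})" if need else s)
    return f"{parts[0]} {rule.op} {parts[1]}"


def genes_of(rule: GPRRule) -> frozenset[str]:
    """The set of gene ids appearing in the rule."""
    if isinstance(rule, GeneRef):
        return frozenset([rule.gene])
    return genes_of(rule.left) | genes_of(rule.right)


def dual_gpr(rule: GPRRule) -> GPRRule:
    """Swap every ``and`` with ``or`` (De-Morgan dual)."""
    if isinstance(rule, GeneRef):
        return rule
    return BoolOp("or" if rule.op == "and" else "and",
                  dual_gpr(rule.left), dual_gpr(rule.right))


def evaluate_gpr(rule: GPRRule, gene_states: Mapping[str, int]) -> int:
    """Evaluate a rule over three-valued gene states.

    Leaves take the gene's state; a gene absent from ``gene_states`` is
    treated as 0 (no evidence).  ``and`` = min, ``or`` = max over the order
    -1 < 0 < +1.
    """
    if isinstance(rule, GeneRef):
        return int(gene_states.get(rule.gene, 0))
    a = evaluate_gpr(rule.left, gene_states)
    b = evaluate_gpr(rule.right, gene_states)
    return min(a, b) if rule.op == "and" else max(a, b)
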