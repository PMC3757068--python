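"""Boolean gene-protein-reaction (GPR) rules.

Grammar: identifiers, ``and``/``or`` (case-insensitive), parentheses;
``and`` binds tighter than ``or``.  An empty rule means the reaction has no
genetic requirement.

The same expression tree drives three evaluations:

* gene extraction (which genes a reaction depends on),
* Boolean availability under a gene knockout (AND = enzyme complex,
  OR = isozymes), and
* penalty propagation for expression integration (AND -> max of member
  penalties, the complex is limited by its least-expressed subunit;
  OR -> min, any sufficiently expressed isozyme carries the flux).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional

from .exceptions import GprParseError

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or"}


@dataclass(frozen=True)
class GprNode:
    """Node of a parsed GPR expression tree.

    ``op`` is ``"gene"``, ``"and"`` or ``"or"``; leaves carry ``gene``,
    internal nodes carry ``children``.
    """

    op: str
    gene: Optional[str] = None
    children: tuple = ()

    @property
    def genes(self) -> frozenset:
        if self.op == "gene":
            return frozenset([self.gene])
        out = frozenset()
        for child in self.children:
            out |= child.genes
        return out

    def evaluate(self, knocked_out: set) -> bool:
        """Availability with the given genes deleted (all others present)."""
        if self.op == "gene":
            return self.gene not in knocked_out
        if self.op == "and":
            return all(c.evaluate(knocked_out) for c in self.children)
        return any(c.evaluate(knocked_out) for c in self.children)

    def penalty(self, gene_penalties: Mapping[str, float]) -> float:
        """Propagate per-gene penalties to a reaction penalty.

        Genes missing from the mapping contribute 0 (no evidence, no
        penalty).
        """
        if self.op == "gene":
            return float(gene_penalties.get(self.gene, 0.0))
        values = [c.penalty(gene_penalties) for c in self.children]
        return max(values) if self.op == "and" else min(values)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for child in self.children:
            text = child.to_string()
            # parenthesize an OR child under an AND parent (and vice versa)
            if child.op != "gene" and child.op != self.op:
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)


def _tokenize(text: str) -> list:
    tokens = _TOKEN_RE.findall(text)
    return tokens


class _Parser:
    def __init__(self, tokens, source):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def fail(self, msg):
        raise GprParseError(f"invalid GPR {self.source!r}: {msg}")

    def parse_expression(self) -> GprNode:
        node = self.parse_term()
        children = [node]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            children.append(self.parse_term())
        if len(children) == 1:
            return node
        return GprNode("or", children=tuple(children))

    def parse_term(self) -> GprNode:
        node = self.parse_factor()
        children = [node]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            children.append(self.parse_factor())
        if len(children) == 1:
            return node
        return GprNode("and", children=tuple(children))

    def parse_factor(self) -> GprNode:
        tok = self.next()
        if tok is None:
            self.fail("unexpected end of rule")
        if tok == "(":
            node = self.parse_expression()
            if self.next() != ")":
                self.fail("unbalanced parentheses")
            return node
        if tok == ")" or tok.lower() in _KEYWORDS:
            self.fail(f"unexpected token {tok!r}")
        return GprNode("gene", gene=tok)


def parse_gpr(text: Optional[str]) -> Optional[GprNode]:
    """Parse a GPR rule; returns ``None`` for an empty rule."""
    if text is None or not text.strip():
        return None
    tokens = _tokenize(text)
    parser = _Parser(tokens, text)
    node = parser.parse_expression()
    if parser.peek() is not None:
        parser.fail(f"trailing token {parser.peek()!r}")
    return node
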