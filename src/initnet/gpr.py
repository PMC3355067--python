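"""Boolean gene-reaction association expressions.

A GPR is a tree of AND/OR nodes over gene identifiers.  ``None`` denotes the
empty association (a reaction with no gene).  The grammar is case-insensitive
``and`` / ``or`` with parentheses; AND binds tighter than OR, matching common
genome-scale-model conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Union

__all__ = [
    "Gene",
    "And",
    "Or",
    "GPRNode",
    "parse_gpr",
    "gpr_to_string",
    "gpr_genes",
    "evaluate_gpr",
    "prune_gpr",
]


@dataclass(frozen=True)
class Gene:
    """Leaf node: a single gene identifier."""

    id: str


@dataclass(frozen=True)
class And:
    children: tuple

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("And node requires at least two children")


@dataclass(frozen=True)
class Or:
    children: tuple

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("Or node requires at least two children")


GPRNode = Union[Gene, And, Or]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GPRParseError(ValueError):
    pass


def _tokens(text: str) -> Iterator[str]:
    for match in _TOKEN_RE.finditer(text):
        yield match.group(0)


def parse_gpr(text: Optional[str]) -> Optional[GPRNode]:
    """Parse a GPR string into a tree; empty/blank input gives ``None``."""
    if text is None:
        return None
    text = text.strip()
    if not text:
        return None
    toks = list(_tokens(text))
    pos = 0

    def peek() -> Optional[str]:
        return toks[pos] if pos < len(toks) else None

    def advance() -> str:
        nonlocal pos
        tok = toks[pos]
        pos += 1
        return tok

    def parse_or() -> GPRNode:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            advance()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and() -> GPRNode:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            advance()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR expression: {text!r}")
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parenthesis in GPR: {text!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        return Gene(advance())

    node = parse_or()
    if pos != len(toks):
        raise GPRParseError(f"trailing tokens in GPR: {text!r}")
    return node


def gpr_to_string(node: Optional[GPRNode]) -> str:
    if node is None:
        return ""
    if isinstance(node, Gene):
        return node.id
    op = " and " if isinstance(node, And) else " or "
    parts = []
    for child in node.children:
        s = gpr_to_string(child)
        if not isinstance(child, Gene):
            s = f"({s})"
        parts.append(s)
    return op.join(parts)


def gpr_genes(node: Optional[GPRNode]) -> set:
    """Set of gene ids appearing in the expression."""
    if node is None:
        return set()
    if isinstance(node, Gene):
        return {node.id}
    out: set = set()
    for child in node.children:
        out |= gpr_genes(child)
    return out


def evaluate_gpr(node: Optional[GPRNode], active: set) -> bool:
    """Evaluate the boolean expression with ``active`` genes set to True."""
    if node is None:
        return False
    if isinstance(node, Gene):
        return node.id in active
    results = (evaluate_gpr(c, active) for c in node.children)
    return all(results) if isinstance(node, And) else any(results)


def prune_gpr(
    node: Optional[GPRNode], gene_scores: Mapping[str, float]
) -> Optional[GPRNode]:
    """Restrict a GPR to genes with strictly positive evidence score.

    Genes missing from ``gene_scores`` are treated as non-positive.  Returns
    ``None`` when no positive-evidence gene remains.
    """
    if node is None:
        return None
    if isinstance(node, Gene):
        return node if gene_scores.get(node.id, 0.0) > 0 else None
    kept = tuple(
        c for c in (prune_gpr(child, gene_scores) for child in node.children)
        if c is not None
    )
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return And(kept) if isinstance(node, And) else Or(kept)
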