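"""Gene-protein-reaction (GPR) Boolean rules.

A GPR rule is a Boolean expression over gene identifiers in which ``and``
denotes an enzymatic complex (all gene products required) and ``or`` denotes
isoenzymes (alternative catalysts). Rules are parsed into small immutable
trees; the quantitative evaluation of a tree against expression data lives in
:mod:`transflux.expression`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["GPRNode", "GPRParseError", "parse_gpr", "gpr_to_string", "gpr_genes"]


class GPRParseError(ValueError):
    """Raised when a GPR rule string is syntactically invalid."""


@dataclass(frozen=True)
class GPRNode:
    """A node of a parsed GPR tree.

    ``kind`` is ``"gene"`` (leaf, carries ``gene_id``), ``"and"`` or ``"or"``
    (internal, carries at least two ``children``). Trees are finite and
    acyclic by construction.
    """

    kind: str
    gene_id: Optional[str] = None
    children: tuple["GPRNode", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "gene":
            if not self.gene_id or self.children:
                raise ValueError("gene leaf must carry exactly one gene id")
        elif self.kind in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind!r} node needs >= 2 children")
            if self.gene_id is not None:
                raise ValueError("internal node cannot carry a gene id")
        else:
            raise ValueError(f"unknown GPR node kind {self.kind!r}")


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(rule: str) -> list[str]:
    return _TOKEN_RE.findall(rule)


def parse_gpr(rule: str) -> Optional[GPRNode]:
    """Parse a GPR rule string into a :class:`GPRNode` tree.

    ``and``/``or`` are case-insensitive; ``and`` binds tighter than ``or``
    (COBRA convention) where parentheses are absent. Consecutive same-operator
    terms are flattened into a single n-ary node. An empty or blank rule
    returns ``None`` (no gene association).

    Raises
    ------
    GPRParseError
        On unbalanced parentheses, dangling operators or empty operands.
    """
    if rule is None or not rule.strip():
        return None
    tokens = _tokenize(rule)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def fail(msg: str) -> GPRParseError:
        return GPRParseError(f"{msg} in GPR rule {rule!r}")

    def parse_or() -> GPRNode:
        nonlocal pos
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return _flatten("or", terms)

    def parse_and() -> GPRNode:
        nonlocal pos
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            factors.append(parse_atom())
        if len(factors) == 1:
            return factors[0]
        return _flatten("and", factors)

    def parse_atom() -> GPRNode:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise fail("unexpected end of rule")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise fail("unbalanced parentheses")
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise fail(f"empty operand before {tok!r}")
        pos += 1
        return GPRNode("gene", gene_id=tok)

    tree = parse_or()
    if pos != len(tokens):
        raise fail(f"trailing tokens starting at {tokens[pos]!r}")
    return tree


def _flatten(kind: str, nodes: list[GPRNode]) -> GPRNode:
    children: list[GPRNode] = []
    for n in nodes:
        if n.kind == kind:
            children.extend(n.children)
        else:
            children.append(n)
    return GPRNode(kind, children=tuple(children))


def gpr_to_string(node: Optional[GPRNode]) -> str:
    """Serialise a tree back to a canonical, fully parenthesised rule string."""
    if node is None:
        return ""
    if node.kind == "gene":
        return node.gene_id
    sep = f" {node.kind} "
    return "(" + sep.join(gpr_to_string(c) for c in node.children) + ")"


def gpr_genes(node: Optional[GPRNode]) -> set[str]:
    """All gene identifiers appearing in the tree."""
    if node is None:
        return set()
    if node.kind == "gene":
        return {node.gene_id}
    out: set[str] = set()
    for c in node.children:
        out |= gpr_genes(c)
    return out
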