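"""Gene-protein-reaction (GPR) rules: parsing and numeric evaluation.

A GPR rule is a Boolean combination of gene identifiers with AND / OR.
For expression integration the Boolean semantics are replaced by the
standard numeric ones: an enzyme complex (AND) is limited by its least
expressed subunit, so AND maps to ``min``; isozymes (OR) act additively
in capacity but are conventionally summarised by the dominant one, so
OR maps to ``max``.

Genes missing from the expression table are treated as *missing data*,
not as zero expression: they are dropped from their operator's argument
list, and a node whose children all fail to resolve is itself
unresolved. A rule where no leaf resolves evaluates to "unmapped".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Union

__all__ = ["Gene", "And", "Or", "GPRNode", "parse_gpr", "eval_gpr", "gpr_genes"]


@dataclass(frozen=True)
class Gene:
    name: str

    def to_string(self) -> str:
        return self.name


@dataclass(frozen=True)
class And:
    children: tuple["GPRNode", ...]

    def to_string(self) -> str:
        return " and ".join(_child_str(c, And) for c in self.children)


@dataclass(frozen=True)
class Or:
    children: tuple["GPRNode", ...]

    def to_string(self) -> str:
        return " or ".join(_child_str(c, Or) for c in self.children)


GPRNode = Union[Gene, And, Or]


def _child_str(node: GPRNode, parent_type: type) -> str:
    if isinstance(node, Gene) or isinstance(node, parent_type):
        return node.to_string()
    return f"({node.to_string()})"


class GPRParseError(ValueError):
    """Raised when a GPR string is not a valid AND/OR expression."""


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str) -> Optional[GPRNode]:
    """Parse a GPR rule string into an expression tree.

    AND binds tighter than OR (the cobra/SBML-FBC convention). Keywords
    are matched case-insensitively; ``&``/``|`` are accepted as synonyms.
    Returns ``None`` for an empty rule.
    """
    tokens = _TOKEN_RE.findall(rule)
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def is_kw(tok: Optional[str], *kws: str) -> bool:
        return tok is not None and tok.lower() in kws

    def parse_or() -> GPRNode:
        terms = [parse_and()]
        while is_kw(peek(), "or", "|", "||"):
            advance()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and() -> GPRNode:
        factors = [parse_atom()]
        while is_kw(peek(), "and", "&", "&&"):
            advance()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR rule: {rule!r}")
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parenthesis in GPR rule: {rule!r}")
            advance()
            return node
        if tok == ")" or is_kw(tok, "and", "or", "&", "|", "&&", "||"):
            raise GPRParseError(f"misplaced token {tok!r} in GPR rule: {rule!r}")
        return Gene(advance())

    tree = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR rule: {rule!r}")
    return tree


def eval_gpr(node: Optional[GPRNode], gene_values: Mapping[str, float]) -> Optional[float]:
    """Evaluate a GPR tree against gene expression values.

    AND -> min of resolved children, OR -> max of resolved children;
    unresolved children are dropped. Returns ``None`` (unmapped) when no
    leaf resolves, or when ``node`` is ``None`` (no rule).
    """
    if node is None:
        return None
    if isinstance(node, Gene):
        val = gene_values.get(node.name)
        return float(val) if val is not None else None
    vals = [v for v in (eval_gpr(c, gene_values) for c in node.children) if v is not None]
    if not vals:
        return None
    return min(vals) if isinstance(node, And) else max(vals)


def gpr_genes(node: Optional[GPRNode]) -> set[str]:
    """All gene identifiers appearing in a GPR tree."""
    if node is None:
        return set()
    if isinstance(node, Gene):
        return {node.name}
    out: set[str] = set()
    for c in node.children:
        out |= gpr_genes(c)
    return out
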