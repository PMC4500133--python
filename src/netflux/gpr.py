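"""Boolean gene-reaction association rules (AND/OR expressions over gene IDs).

Two evaluation modes are needed downstream and deliberately kept separate:

* Boolean — is the reaction catalysable given a set of inactive genes?
  Used by the knockout simulator.
* Numeric — map gene expression onto a reaction-level activity proxy with
  AND -> min and OR -> max.  Used to weight the flux-minimization objective.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)

# AST nodes: ("gene", name) | ("and", [children]) | ("or", [children])
Ast = tuple


def parse_gpr(rule: str) -> Ast | None:
    """Parse a boolean rule string into an AST; ``None`` for an empty rule.

    Grammar (OR binds loosest, standard for gene association strings)::

        expr   := term ( OR term )*
        term   := factor ( AND factor )*
        factor := GENE | '(' expr ')'
    """
    tokens = _TOKEN.findall(rule or "")
    if not tokens:
        return None
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def expr() -> Ast:
        terms = [term()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(term())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def term() -> Ast:
        factors = [factor()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(factor())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def factor() -> Ast:
        tok = peek()
        if tok is None:
            raise ValueError(f"truncated GPR rule: {rule!r}")
        if tok == "(":
            take()
            node = expr()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in GPR rule: {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"unexpected {tok!r} in GPR rule: {rule!r}")
        return ("gene", take())

    tree = expr()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR rule: {rule!r}")
    return tree


def gpr_genes(ast: Ast | None) -> set[str]:
    if ast is None:
        return set()
    kind = ast[0]
    if kind == "gene":
        return {ast[1]}
    return set().union(*(gpr_genes(child) for child in ast[1]))


def eval_gpr_bool(ast: Ast | None, inactive: Iterable[str]) -> bool:
    """Reaction availability with genes in ``inactive`` switched off.

    An empty rule means the reaction has no gene requirement and stays on.
    """
    if ast is None:
        return True
    off = set(inactive)

    def rec(node: Ast) -> bool:
        kind = node[0]
        if kind == "gene":
            return node[1] not in off
        if kind == "and":
            return all(rec(c) for c in node[1])
        return any(rec(c) for c in node[1])

    return rec(ast)


def eval_gpr_numeric(ast: Ast | None, expression: Mapping[str, float]) -> float | None:
    """AND -> min, OR -> max over gene expression; ``None`` for an empty rule."""
    if ast is None:
        return None

    def rec(node: Ast) -> float:
        kind = node[0]
        if kind == "gene":
            return float(expression[node[1]])
        values = [rec(c) for c in node[1]]
        return min(values) if kind == "and" else max(values)

    return rec(ast)


def format_gpr(ast: Ast | None) -> str:
    if ast is None:
        return ""
    kind = ast[0]
    if kind == "gene":
        return ast[1]
    joiner = " and " if kind == "and" else " or "
    parts = []
    for child in ast[1]:
        text = format_gpr(child)
        if child[0] != "gene":
            text = f"({text})"
        parts.append(text)
    return joiner.join(parts)
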