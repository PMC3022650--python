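"""Gene-protein-reaction (GPR) boolean rules.

A rule is an OR of AND-groups over gene loci, written with ``&`` for enzyme
complexes (e.g. ``Pcar_2542 & Pcar_2543``) and ``or`` for isozymes; parentheses
are allowed. The empty rule denotes a non-gene-associated reaction.
"""

from __future__ import annotations

import re

__all__ = ["MalformedGPRError", "parse_gpr", "evaluate_ast", "genes_in"]

_TOKEN = re.compile(r"\s*(\(|\)|&|\||[A-Za-z0-9_.\-]+)")


class MalformedGPRError(ValueError):
    """Raised when a GPR string cannot be parsed."""


def _tokenize(rule: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if m is None:
            raise MalformedGPRError(f"unexpected character at {pos!r} in {rule!r}")
        tok = m.group(1)
        if tok.lower() == "and":
            tok = "&"
        elif tok.lower() == "or":
            tok = "|"
        tokens.append(tok)
        pos = m.end()
    return tokens


def parse_gpr(rule: str):
    """Parse a GPR rule into an AST.

    Returns ``None`` for the empty rule, else a nested tuple of the form
    ``("gene", id)``, ``("and", [..])`` or ``("or", [..])``.
    """
    if rule is None or not rule.strip():
        return None
    tokens = _tokenize(rule)

    def parse_or(i):
        node, i = parse_and(i)
        terms = [node]
        while i < len(tokens) and tokens[i] == "|":
            node, i = parse_and(i + 1)
            terms.append(node)
        return (terms[0] if len(terms) == 1 else ("or", terms)), i

    def parse_and(i):
        node, i = parse_atom(i)
        factors = [node]
        while i < len(tokens) and tokens[i] == "&":
            node, i = parse_atom(i + 1)
            factors.append(node)
        return (factors[0] if len(factors) == 1 else ("and", factors)), i

    def parse_atom(i):
        if i >= len(tokens):
            raise MalformedGPRError(f"unexpected end of rule in {rule!r}")
        tok = tokens[i]
        if tok == "(":
            node, i = parse_or(i + 1)
            if i >= len(tokens) or tokens[i] != ")":
                raise MalformedGPRError(f"unbalanced parentheses in {rule!r}")
            return node, i + 1
        if tok in ("&", "|", ")"):
            raise MalformedGPRError(f"misplaced {tok!r} in {rule!r}")
        return ("gene", tok), i + 1

    ast, i = parse_or(0)
    if i != len(tokens):
        raise MalformedGPRError(f"trailing tokens in {rule!r}")
    return ast


def evaluate_ast(ast, expressed: set[str]) -> bool:
    """True iff the boolean rule is satisfied by the expressed gene set."""
    if ast is None:
        return True
    kind = ast[0]
    if kind == "gene":
        return ast[1] in expressed
    if kind == "and":
        return all(evaluate_ast(a, expressed) for a in ast[1])
    return any(evaluate_ast(a, expressed) for a in ast[1])


def genes_in(ast) -> set[str]:
    if ast is None:
        return set()
    if ast[0] == "gene":
        return {ast[1]}
    out: set[str] = set()
    for a in ast[1]:
        out |= genes_in(a)
    return out
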