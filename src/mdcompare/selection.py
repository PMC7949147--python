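"""Atom-selection mini-language.

Grammar (case-insensitive keywords)::

    expr     := or_expr
    or_expr  := and_expr ( "or" and_expr )*
    and_expr := unary ( "and" unary )*
    unary    := "not" unary | "(" expr ")" | term
    term     := "chain" ID | "resid" N [ "-" M ] | "resname" S
              | "name" S | "element" S

Examples: ``chain A``, ``resid 359 and name OE1``, ``resid 380-390``,
``not (chain A)``, ``chain A or chain B``.

Syntax errors raise :class:`~mdcompare.errors.SelectionSyntaxError` carrying
the character position.  Matching is exact and case-sensitive for values
(atom and residue names are stored as the source file wrote them).
"""

from __future__ import annotations

import re
from typing import Callable

import numpy as np

from .core import AtomSelection, Topology
from .errors import SelectionSyntaxError

__all__ = ["select"]

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")
_KEYWORDS = {"and", "or", "not", "chain", "resid", "resname", "name", "element"}


class _Token:
    __slots__ = ("text", "pos")

    def __init__(self, text: str, pos: int):
        self.text = text
        self.pos = pos


def _tokenize(expression: str) -> list[_Token]:
    tokens = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            break
        tokens.append(_Token(m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser producing a mask-evaluating closure."""

    def __init__(self, expression: str, topology: Topology):
        self.expression = expression
        self.topology = topology
        self.tokens = _tokenize(expression)
        self.i = 0

    def _peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> _Token:
        tok = self._peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression",
                                       len(self.expression))
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionSyntaxError("empty selection expression", 0)
        mask = self._or_expr()
        tok = self._peek()
        if tok is not None:
            raise SelectionSyntaxError(f"unexpected token {tok.text!r}", tok.pos)
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while (tok := self._peek()) is not None and tok.text.lower() == "or":
            self._next()
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._unary()
        while (tok := self._peek()) is not None and tok.text.lower() == "and":
            self._next()
            mask = mask & self._unary()
        return mask

    def _unary(self) -> np.ndarray:
        tok = self._peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression",
                                       len(self.expression))
        if tok.text.lower() == "not":
            self._next()
            return ~self._unary()
        if tok.text == "(":
            self._next()
            mask = self._or_expr()
            closing = self._peek()
            if closing is None or closing.text != ")":
                pos = closing.pos if closing else len(self.expression)
                raise SelectionSyntaxError("expected ')'", pos)
            self._next()
            return mask
        return self._term()

    def _term(self) -> np.ndarray:
        tok = self._next()
        keyword = tok.text.lower()
        top = self.topology
        if keyword not in {"chain", "resid", "resname", "name", "element"}:
            raise SelectionSyntaxError(
                f"expected a selection keyword, got {tok.text!r}", tok.pos)
        value = self._next()
        if value.text in {"(", ")"} or value.text.lower() in _KEYWORDS:
            raise SelectionSyntaxError(
                f"expected a value after {keyword!r}, got {value.text!r}", value.pos)
        if keyword == "chain":
            return np.asarray(top.chain_ids == value.text)
        if keyword == "resname":
            return np.asarray(top.resnames == value.text)
        if keyword == "name":
            return np.asarray(top.names == value.text)
        if keyword == "element":
            return np.asarray(top.elements == value.text.upper())
        # resid N or N-M
        m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", value.text)
        if m is None:
            raise SelectionSyntaxError(
                f"resid expects an integer or range, got {value.text!r}", value.pos)
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if hi < lo:
            raise SelectionSyntaxError(
                f"resid range {value.text!r} is reversed", value.pos)
        return (top.resnums >= lo) & (top.resnums <= hi)


def select(topology: Topology, expression: str) -> AtomSelection:
    """Evaluate a selection expression against a topology.

    Returns an :class:`AtomSelection`; an empty selection is legal.
    Raises :class:`SelectionSyntaxError` (with position) on grammar errors.
    """
    mask = _Parser(expression, topology).parse()
    indices = tuple(int(i) for i in np.flatnonzero(mask))
    return AtomSelection(indices=indices, expression=expression,
                         n_atoms_topology=topology.n_atoms)
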