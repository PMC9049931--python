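"""Atom-selection mini-language.

Expressions combine field tests with ``and`` / ``or`` / ``not`` and
parentheses.  Fields: ``element``, ``name``, ``residue_name``,
``residue_index``, ``molecule_id``.  A field test is the field name
followed by one or more accepted values; the numeric fields also accept
inclusive ranges written ``lo:hi``.  Examples::

    element C and molecule_id 1
    not element H
    residue_index 0:9 30 or name CA
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .core import Trajectory

__all__ = ["SelectionSpec", "SelectionSyntaxError", "select"]

_STRING_FIELDS = {"element", "name", "residue_name"}
_INT_FIELDS = {"residue_index", "molecule_id"}
_FIELDS = _STRING_FIELDS | _INT_FIELDS
_KEYWORDS = {"and", "or", "not", "(", ")"}

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class SelectionSyntaxError(ValueError):
    """Malformed selection expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class _Token:
    text: str
    position: int


def _tokenize(expression: str) -> list[_Token]:
    return [_Token(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]


class _Parser:
    """Recursive-descent parser producing a predicate over atom index."""

    def __init__(self, expression: str):
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.pos = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression",
                                       len(self.expression))
        self.pos += 1
        return tok

    def parse(self):
        if not self.tokens:
            raise SelectionSyntaxError("empty selection expression", 0)
        node = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise SelectionSyntaxError(f"unexpected token {tok.text!r}", tok.position)
        return node

    def parse_or(self):
        left = self.parse_and()
        while (tok := self.peek()) is not None and tok.text == "or":
            self.next()
            right = self.parse_and()
            left = (lambda a, l=left, r=right: l(a) or r(a))
        return left

    def parse_and(self):
        left = self.parse_unary()
        while (tok := self.peek()) is not None and tok.text == "and":
            self.next()
            right = self.parse_unary()
            left = (lambda a, l=left, r=right: l(a) and r(a))
        return left

    def parse_unary(self):
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression",
                                       len(self.expression))
        if tok.text == "not":
            self.next()
            inner = self.parse_unary()
            return lambda a, f=inner: not f(a)
        if tok.text == "(":
            self.next()
            inner = self.parse_or()
            closing = self.next()
            if closing.text != ")":
                raise SelectionSyntaxError("expected ')'", closing.position)
            return inner
        return self.parse_field_test()

    def parse_field_test(self):
        tok = self.next()
        fld = tok.text
        if fld in {")", "("}:
            raise SelectionSyntaxError(f"unexpected {fld!r}", tok.position)
        if fld not in _FIELDS:
            raise SelectionSyntaxError(f"unknown field name {fld!r}", tok.position)

        values: list = []
        ranges: list[tuple[int, int]] = []
        while (nxt := self.peek()) is not None and nxt.text not in _KEYWORDS:
            vtok = self.next()
            if fld in _INT_FIELDS:
                m = re.fullmatch(r"(-?\d+):(-?\d+)", vtok.text)
                if m:
                    ranges.append((int(m.group(1)), int(m.group(2))))
                elif re.fullmatch(r"-?\d+", vtok.text):
                    values.append(int(vtok.text))
                else:
                    raise SelectionSyntaxError(
                        f"field {fld!r} expects integers or lo:hi ranges, "
                        f"got {vtok.text!r}", vtok.position)
            else:
                values.append(vtok.text)
        if not values and not ranges:
            raise SelectionSyntaxError(f"field {fld!r} needs at least one value",
                                       tok.position)

        if fld in _INT_FIELDS:
            vset = set(values)

            def test(atom, fld=fld, vset=vset, ranges=tuple(ranges)):
                v = getattr(atom, fld)
                return v in vset or any(lo <= v <= hi for lo, hi in ranges)
        else:
            if fld == "element":
                vset = {v[0].upper() + v[1:].lower() for v in values}
            else:
                vset = set(values)

            def test(atom, fld=fld, vset=vset):
                return getattr(atom, fld) in vset

        return test


@dataclass(frozen=True)
class SelectionSpec:
    """A parsed selection expression (parse errors raise at construction)."""

    expression: str

    def __post_init__(self):
        object.__setattr__(self, "_predicate", _Parser(self.expression).parse())

    def evaluate(self, topology) -> np.ndarray:
        """Sorted, duplicate-free 0-based atom indices matching the spec."""
        pred = self._predicate
        return np.array([a.index for a in topology if pred(a)], dtype=int)


def select(trajectory: Trajectory, spec: SelectionSpec | str) -> np.ndarray:
    """Evaluate a selection against a trajectory's topology."""
    if isinstance(spec, str):
        spec = SelectionSpec(spec)
    return spec.evaluate(trajectory.topology)
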