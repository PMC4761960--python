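"""A small boolean selection language over atom fields.

Grammar::

    expr       := term ("or" term)*
    term       := factor ("and" factor)*
    factor     := "(" expr ")" | "not" factor | comparison
    comparison := FIELD ("==" | "!=") VALUE

Fields: ``residue_name``, ``residue_id``, ``chain``, ``element``, ``group``,
``name``.  Values are bare tokens (``PHE``, ``228``, ``cnt``).  Matching on
``residue_name``, ``element`` and ``name`` is case-insensitive; ``group``
looks up the structure's named groups and raises on unknown names.
"""
from __future__ import annotations

import re
from typing import Iterator, NamedTuple

import numpy as np

from .model import Selection, Structure

__all__ = ["resolve_selection", "SelectionError", "SelectionSyntaxError"]


class SelectionError(ValueError):
    """Semantic selection failure (e.g. unknown group name)."""


class SelectionSyntaxError(SelectionError):
    """Malformed expression; carries the character position of the problem."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


FIELDS = ("residue_name", "residue_id", "chain", "element", "group", "name")

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<op>==|!=)|(?P<word>[^\s()=!]+))"
)


class _Token(NamedTuple):
    kind: str
    text: str
    pos: int


def _tokenize(expression: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            stripped = expression[pos:].lstrip()
            if not stripped:
                break
            raise SelectionSyntaxError(
                f"unexpected character {expression[pos:pos+1]!r}", pos
            )
        pos = m.end()
        for kind in ("lpar", "rpar", "op", "word"):
            text = m.group(kind)
            if text is not None:
                tokens.append(_Token(kind, text, m.start(kind)))
                break
    return tokens


class _Parser:
    def __init__(self, expression: str, structure: Structure):
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.i = 0
        self.structure = structure
        self._columns: dict[str, np.ndarray] = {}

    def _peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> _Token:
        tok = self._peek()
        if tok is None:
            raise SelectionSyntaxError(
                "unexpected end of expression", len(self.expression)
            )
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionSyntaxError("empty expression", 0)
        mask = self._expr()
        tok = self._peek()
        if tok is not None:
            raise SelectionSyntaxError(f"unexpected token {tok.text!r}", tok.pos)
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while True:
            tok = self._peek()
            if tok is not None and tok.kind == "word" and tok.text.lower() == "or":
                self._next()
                mask = mask | self._term()
            else:
                return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while True:
            tok = self._peek()
            if tok is not None and tok.kind == "word" and tok.text.lower() == "and":
                self._next()
                mask = mask & self._factor()
            else:
                return mask

    def _factor(self) -> np.ndarray:
        tok = self._peek()
        if tok is None:
            raise SelectionSyntaxError(
                "unexpected end of expression", len(self.expression)
            )
        if tok.kind == "lpar":
            self._next()
            mask = self._expr()
            closing = self._peek()
            if closing is None or closing.kind != "rpar":
                raise SelectionSyntaxError(
                    "missing closing parenthesis",
                    closing.pos if closing else len(self.expression),
                )
            self._next()
            return mask
        if tok.kind == "word" and tok.text.lower() == "not":
            self._next()
            return ~self._factor()
        return self._comparison()

    def _comparison(self) -> np.ndarray:
        field_tok = self._next()
        if field_tok.kind != "word" or field_tok.text not in FIELDS:
            raise SelectionSyntaxError(
                f"expected one of {FIELDS}, got {field_tok.text!r}", field_tok.pos
            )
        op_tok = self._next()
        if op_tok.kind != "op":
            raise SelectionSyntaxError(
                f"expected '==' or '!=' after {field_tok.text}", op_tok.pos
            )
        value_tok = self._next()
        if value_tok.kind != "word":
            raise SelectionSyntaxError("expected a value", value_tok.pos)
        mask = self._match(field_tok.text, value_tok.text, value_tok.pos)
        return ~mask if op_tok.text == "!=" else mask

    def _column(self, field: str) -> np.ndarray:
        if field not in self._columns:
            atoms = self.structure.atoms
            if field == "residue_name":
                col = np.array([a.residue_name.upper() for a in atoms])
            elif field == "residue_id":
                col = np.array([a.residue_id for a in atoms])
            elif field == "chain":
                col = np.array([a.chain_id for a in atoms])
            elif field == "element":
                col = np.array([a.element.upper() for a in atoms])
            elif field == "name":
                col = np.array([a.name.upper() for a in atoms])
            else:  # pragma: no cover - guarded by FIELDS
                raise AssertionError(field)
            self._columns[field] = col
        return self._columns[field]

    def _match(self, field: str, value: str, pos: int) -> np.ndarray:
        n = self.structure.n_atoms
        if field == "group":
            if value not in self.structure.groups:
                known = sorted(self.structure.groups)
                raise SelectionError(
                    f"unknown group {value!r}; known groups: {known}"
                )
            mask = np.zeros(n, dtype=bool)
            mask[list(self.structure.groups[value])] = True
            return mask
        if field == "residue_id":
            try:
                rid = int(value)
            except ValueError:
                raise SelectionSyntaxError(
                    f"residue_id requires an integer, got {value!r}", pos
                ) from None
            return self._column(field) == rid
        if field == "chain":
            return self._column(field) == value
        return self._column(field) == value.upper()


def resolve_selection(structure: Structure, expression: str) -> Selection:
    """Resolve ``expression`` against ``structure``.

    Deterministic and idempotent; an expression matching nothing yields an
    empty Selection rather than an error.
    """
    mask = _Parser(expression, structure).parse()
    return Selection(expression=expression, resolved=frozenset(np.flatnonzero(mask)))
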