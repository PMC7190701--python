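"""A small atom-selection language over :class:`MolecularSystem`.

Grammar (case-insensitive keywords, ``not`` binds tightest, then ``and``, then ``or``)::

    expr    := term ("or" term)*
    term    := factor ("and" factor)*
    factor  := "not" factor | "(" expr ")" | primary
    primary := "all" | "none"
             | "resid"   (INT | INT-INT)+
             | "name"    WORD+
             | "resname" WORD+
             | "element" WORD+
             | "chain"   WORD+
             | "segid"   WORD+
             | "moltag"  WORD+

Examples: ``resid 50-490 and name CA``, ``moltag lipid``,
``(resname HEM and name NA NB NC ND) or element FE``.

Evaluation returns a sorted integer index array; the same expression on the same
system always yields the same set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .io_structures import MolecularSystem

__all__ = ["select", "SelectionError"]


class SelectionError(ValueError):
    """Unknown token or malformed selection expression (reports position)."""


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")

_KEYWORDS = {"resid", "name", "resname", "element", "chain", "segid", "moltag"}
_RANGE_RE = re.compile(r"^(-?\d+)-(-?\d+)$")


@dataclass
class _Token:
    text: str
    pos: int


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
    def __init__(self, expression: str, system: MolecularSystem):
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.i = 0
        self.system = system
        self._moltags: np.ndarray | None = None

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection {self.expression!r}")
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression")
        mask = self.expr()
        if self.peek() is not None:
            tok = self.peek()
            raise SelectionError(f"unexpected token {tok.text!r} at position {tok.pos}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while (tok := self.peek()) is not None and tok.text.lower() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while (tok := self.peek()) is not None and tok.text.lower() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection {self.expression!r}")
        if tok.text.lower() == "not":
            self.next()
            return ~self.factor()
        if tok.text == "(":
            self.next()
            mask = self.expr()
            closing = self.next()
            if closing.text != ")":
                raise SelectionError(f"expected ')' at position {closing.pos}, got {closing.text!r}")
            return mask
        return self.primary()

    def primary(self) -> np.ndarray:
        tok = self.next()
        key = tok.text.lower()
        n = self.system.n_atoms
        if key == "all":
            return np.ones(n, dtype=bool)
        if key == "none":
            return np.zeros(n, dtype=bool)
        if key not in _KEYWORDS:
            raise SelectionError(f"unknown token {tok.text!r} at position {tok.pos}")
        values = self._values(key)
        if key == "resid":
            mask = np.zeros(n, dtype=bool)
            resids = self.system.resids
            for lo, hi in values:
                mask |= (resids >= lo) & (resids <= hi)
            return mask
        column = {
            "name": self.system.names,
            "resname": self.system.resnames,
            "element": self.system.elements,
            "chain": self.system.chains,
            "segid": self.system.segids,
        }.get(key)
        if key == "moltag":
            if self._moltags is None:
                self._moltags = self.system.moltags()
            column = self._moltags
        return np.isin(column, list(values))

    def _values(self, key: str):
        vals = []
        while (tok := self.peek()) is not None:
            text = tok.text
            low = text.lower()
            if low in _KEYWORDS or low in ("and", "or", "not", "all", "none") or text in "()":
                break
            self.next()
            if key == "resid":
                m = _RANGE_RE.match(text)
                if m:
                    vals.append((int(m.group(1)), int(m.group(2))))
                else:
                    try:
                        v = int(text)
                    except ValueError:
                        raise SelectionError(
                            f"expected integer or range after 'resid', got {text!r} at position {tok.pos}"
                        ) from None
                    vals.append((v, v))
            else:
                vals.append(text)
        if not vals:
            raise SelectionError(f"keyword {key!r} requires at least one value")
        return vals


def select(system: MolecularSystem, expression: str) -> np.ndarray:
    """Evaluate a selection expression, returning sorted atom indices."""
    mask = _Parser(expression, system).parse()
    return np.flatnonzero(mask)
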