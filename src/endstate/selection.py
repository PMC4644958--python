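"""A small atom-selection language.

Grammar (case-insensitive keywords)::

    expr     := or_expr
    or_expr  := and_expr ( "or" and_expr )*
    and_expr := not_expr ( "and" not_expr )*
    not_expr := "not" not_expr | primary
    primary  := "(" expr ")"
              | "all" | "backbone" | "heavy" | "hydrogen"
              | "chain" <id>
              | "resid" <n> | "resid" <a>:<b>
              | "resname" <name>
              | "name" <name>
              | "element" <symbol>
              | "within" <R> "of" not_expr
              | <group name>                     (caller-supplied index sets)

``backbone`` matches the protein backbone atom-name set {N, CA, C, O};
``heavy`` matches non-hydrogen elements. ``within R of X`` selects atoms
whose minimum distance to any atom of X is <= R Å, evaluated on a single
designated reference frame (membership is frozen there, never per-frame).
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

import numpy as np

from .core import BACKBONE_NAMES, Frame, Topology
from .exceptions import SelectionError

_TOKEN_RE = re.compile(r"\s*([()]|[^\s()]+)")

_KEYWORDS = {
    "and", "or", "not", "all", "backbone", "heavy", "hydrogen",
    "chain", "resid", "resname", "name", "element", "within", "of",
}


class _Tokens:
    def __init__(self, text: str):
        self.text = text
        self.items: list[tuple[str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m:
                break
            self.items.append((m.group(1), m.start(1)))
            pos = m.end()
        self.i = 0

    def peek(self) -> tuple[str, int] | None:
        return self.items[self.i] if self.i < len(self.items) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok


class _Parser:
    def __init__(self, topology: Topology, text: str,
                 frame: Frame | None,
                 groups: Mapping[str, Sequence[int]] | None):
        self.topology = topology
        self.frame = frame
        self.groups = {k.lower(): frozenset(v) for k, v in (groups or {}).items()}
        self.tokens = _Tokens(text)

    # each production returns a frozenset of atom indices
    def parse(self) -> frozenset[int]:
        result = self.or_expr()
        tok = self.tokens.peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok[0]!r}", tok[1])
        return result

    def or_expr(self) -> frozenset[int]:
        result = self.and_expr()
        while True:
            tok = self.tokens.peek()
            if tok and tok[0].lower() == "or":
                self.tokens.next()
                result = result | self.and_expr()
            else:
                return result

    def and_expr(self) -> frozenset[int]:
        result = self.not_expr()
        while True:
            tok = self.tokens.peek()
            if tok and tok[0].lower() == "and":
                self.tokens.next()
                result = result & self.not_expr()
            else:
                return result

    def not_expr(self) -> frozenset[int]:
        tok = self.tokens.peek()
        if tok and tok[0].lower() == "not":
            self.tokens.next()
            universe = frozenset(range(self.topology.n_atoms))
            return universe - self.not_expr()
        return self.primary()

    def _arg(self, what: str) -> tuple[str, int]:
        tok = self.tokens.peek()
        if tok is None:
            raise SelectionError(f"expected {what}", len(self.tokens.text))
        return self.tokens.next()

    def primary(self) -> frozenset[int]:
        word, pos = self._arg("expression")
        low = word.lower()
        atoms = self.topology.atoms
        if word == "(":
            inner = self.or_expr()
            tok = self.tokens.peek()
            if tok is None or tok[0] != ")":
                raise SelectionError("expected ')'", tok[1] if tok else len(self.tokens.text))
            self.tokens.next()
            return inner
        if word == ")":
            raise SelectionError("unexpected ')'", pos)
        if low == "all":
            return frozenset(range(len(atoms)))
        if low == "backbone":
            return frozenset(i for i, a in enumerate(atoms) if a.name in BACKBONE_NAMES)
        if low == "heavy":
            return frozenset(i for i, a in enumerate(atoms) if not a.is_hydrogen)
        if low == "hydrogen":
            return frozenset(i for i, a in enumerate(atoms) if a.is_hydrogen)
        if low == "chain":
            val, _ = self._arg("chain id")
            return frozenset(i for i, a in enumerate(atoms) if a.chain_id == val)
        if low == "resname":
            val, _ = self._arg("residue name")
            return frozenset(
                i for i, a in enumerate(atoms) if a.residue_name.upper() == val.upper()
            )
        if low == "name":
            val, _ = self._arg("atom name")
            return frozenset(i for i, a in enumerate(atoms) if a.name.upper() == val.upper())
        if low == "element":
            val, _ = self._arg("element symbol")
            return frozenset(
                i for i, a in enumerate(atoms) if a.element.upper() == val.upper()
            )
        if low == "resid":
            val, vpos = self._arg("residue number or range")
            try:
                if ":" in val:
                    a_s, b_s = val.split(":", 1)
                    lo, hi = int(a_s), int(b_s)
                else:
                    lo = hi = int(val)
            except ValueError as exc:
                raise SelectionError(f"bad residue range {val!r}", vpos) from exc
            return frozenset(
                i for i, a in enumerate(atoms) if lo <= a.residue_seq <= hi
            )
        if low == "within":
            val, vpos = self._arg("distance")
            try:
                radius = float(val)
            except ValueError as exc:
                raise SelectionError(f"bad distance {val!r}", vpos) from exc
            kw, kpos = self._arg("'of'")
            if kw.lower() != "of":
                raise SelectionError(f"expected 'of', got {kw!r}", kpos)
            other = self.not_expr()
            if self.frame is None:
                raise SelectionError("'within' requires a reference frame", pos)
            return self._within(radius, other)
        if low in self.groups:
            return self.groups[low]
        if low in _KEYWORDS:
            raise SelectionError(f"misplaced keyword {word!r}", pos)
        raise SelectionError(f"unknown selection term {word!r}", pos)

    def _within(self, radius: float, other: frozenset[int]) -> frozenset[int]:
        """Residue-granular proximity: a residue is in when the minimum
        heavy-atom distance between it and the target set is <= R; all of the
        residue's atoms are then included (combine with ``heavy`` to drop
        hydrogens)."""
        if not other:
            return frozenset()
        atoms = self.topology.atoms
        coords = self.frame.coordinates
        target = [i for i in sorted(other) if not atoms[i].is_hydrogen] or sorted(other)
        ref = coords[target]
        out: set[int] = set()
        for _key, members in self.topology.residues().items():
            probe = [i for i in members if not atoms[i].is_hydrogen] or members
            d = np.linalg.norm(coords[probe][:, None, :] - ref[None, :, :], axis=-1)
            if d.min() <= radius:
                out.update(members)
        return frozenset(out)


def select(
    topology: Topology,
    expression: str,
    frame: Frame | None = None,
    groups: Mapping[str, Sequence[int]] | None = None,
) -> frozenset[int]:
    """Evaluate a selection expression against a topology.

    ``frame`` is the designated reference frame for ``within`` terms (pocket
    membership is frozen on it). ``groups`` supplies named index sets (e.g.
    ``{"ligand": [...]}``) usable as terms in the expression.
    """
    return _Parser(topology, expression, frame, groups).parse()
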