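"""Degenerate protein-motif notation: parsing and scanning.

The notation follows the convention used for transcarbamylase
signatures: a bare capital letter is an invariant (predominant)
residue, ``X`` matches any residue, and a parenthesized group such as
``(L/f/v/i/m)`` lists alternatives where capitals are predominant and
lower-case letters occur with lower frequency. Examples of in-family
signatures: ``STRT``, ``HCLP``, ``(Y/W)(G/W)(V/L/I)X`` (the
putrescine-specificity 230-loop) and ``(L/f/v/i/m)XX(F/Y/L/M/v)(L/i/m)``
(the C-terminal helix-13 signature).

Matching accepts primary or secondary residues at each position; each
match reports the fraction of non-wildcard positions satisfied by the
primary set, so downstream callers can prefer stronger matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .seq_core import STANDARD_AA, SequenceRecord


class PatternError(ValueError):
    """Raised for malformed motif notation (message carries the offset)."""


@dataclass(frozen=True)
class PositionSpec:
    """One motif position: primary/secondary residue sets or a wildcard."""

    primary: frozenset = frozenset()
    secondary: frozenset = frozenset()
    wildcard: bool = False

    def __post_init__(self) -> None:
        if self.wildcard:
            if self.primary or self.secondary:
                raise PatternError("wildcard position cannot carry residue sets")
        else:
            if not self.primary:
                raise PatternError("non-wildcard position needs a primary set")
            if self.primary & self.secondary:
                raise PatternError("primary and secondary sets overlap")

    def matches(self, residue: str) -> bool:
        # X in the sequence satisfies only wildcard positions.
        if self.wildcard:
            return True
        return residue in self.primary or residue in self.secondary

    def is_primary(self, residue: str) -> bool:
        return residue in self.primary


@dataclass
class MotifPattern:
    id: str
    positions: list[PositionSpec]
    source_text: str

    def __post_init__(self) -> None:
        if not self.positions:
            raise PatternError("pattern has no positions")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class MotifMatch:
    """A located occurrence; ``start``/``end`` are 1-based inclusive."""

    pattern_id: str
    start: int
    end: int
    matched: str
    primary_fraction: float


def parse_pattern(text: str, pattern_id: Optional[str] = None) -> MotifPattern:
    """Compile motif notation into a :class:`MotifPattern`.

    Raises :class:`PatternError` with the character offset for
    unbalanced parentheses, empty groups or illegal characters.
    """
    positions: list[PositionSpec] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "X":
            positions.append(PositionSpec(wildcard=True))
            i += 1
        elif ch.isalpha() and ch.isupper() and ch in STANDARD_AA:
            positions.append(PositionSpec(primary=frozenset(ch)))
            i += 1
        elif ch == "(":
            close = text.find(")", i)
            if close == -1:
                raise PatternError(f"unbalanced parenthesis at offset {i}")
            body = text[i + 1 : close]
            if not body:
                raise PatternError(f"empty group at offset {i}")
            primary, secondary = set(), set()
            for tok in body.split("/"):
                if len(tok) != 1 or tok.upper() not in STANDARD_AA:
                    raise PatternError(
                        f"illegal group token {tok!r} at offset {i}"
                    )
                (primary if tok.isupper() else secondary).add(tok.upper())
            if not primary:
                raise PatternError(f"group at offset {i} has no predominant residue")
            positions.append(
                PositionSpec(primary=frozenset(primary), secondary=frozenset(secondary))
            )
            i = close + 1
        else:
            raise PatternError(f"illegal character {ch!r} at offset {i}")
    if not positions:
        raise PatternError("empty pattern")
    return MotifPattern(id=pattern_id or text, positions=positions, source_text=text)


def render(pattern: MotifPattern) -> str:
    """Inverse of :func:`parse_pattern` (returns the stored notation)."""
    return pattern.source_text


def scan(
    seq: SequenceRecord,
    pattern: MotifPattern,
    window: Optional[tuple[int, int]] = None,
) -> list[MotifMatch]:
    """All matches of ``pattern`` in ``seq``, ordered by start position.

    ``window`` is an optional 1-based closed interval; every reported
    match lies fully inside it. A pattern longer than the window yields
    an empty list. Overlapping matches at different starts are all
    reported.
    """
    m = len(pattern)
    if window is None:
        lo, hi = 1, len(seq)
    else:
        lo, hi = window
        if not (1 <= lo <= hi <= len(seq)):
            raise IndexError(f"window [{lo}, {hi}] outside 1..{len(seq)}")
    matches: list[MotifMatch] = []
    for start in range(lo, hi - m + 2):
        segment = seq.residues[start - 1 : start - 1 + m]
        ok = True
        n_primary = n_nonwild = 0
        for spec, residue in zip(pattern.positions, segment):
            if not spec.matches(residue):
                ok = False
                break
            if not spec.wildcard:
                n_nonwild += 1
                if spec.is_primary(residue):
                    n_primary += 1
        if ok:
            matches.append(
                MotifMatch(
                    pattern_id=pattern.id,
                    start=start,
                    end=start + m - 1,
                    matched=segment,
                    primary_fraction=(n_primary / n_nonwild) if n_nonwild else 1.0,
                )
            )
    return matches
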