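"""Sequence input grammars and the PolymerSequence type.

Peptides use single-letter codes with nonstandard residues in parentheses
("AC(pS)G").  Peptoids use dash-separated multi-letter codes with optional
repeat groups — "(Nme-Npe)3" — which may nest; repeats are expanded before
residue resolution.  Codes are case-sensitive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .chem import (
    PEPTIDE,
    PEPTOID,
    ChemDatabases,
    Residue,
    Terminus,
    default_databases,
)
from .errors import SequenceLengthError, SequenceParseError, UnknownResidueError

MAX_LENGTH = 150


@dataclass(frozen=True)
class PolymerSequence:
    residues: tuple[Residue, ...]
    n_terminus: Terminus
    c_terminus: Terminus

    def __post_init__(self):
        if not 1 <= len(self.residues) <= MAX_LENGTH:
            raise SequenceLengthError(
                f"sequence length must be 1..{MAX_LENGTH}, got {len(self.residues)}"
            )
        classes = {r.polymer_class for r in self.residues}
        if len(classes) != 1:
            raise ValueError(f"mixed polymer classes in one sequence: {sorted(classes)}")
        if self.n_terminus.end != "N" or self.c_terminus.end != "C":
            raise ValueError("termini must be an (N, C) pair")

    @property
    def polymer_class(self) -> str:
        return self.residues[0].polymer_class

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(r.code for r in self.residues)

    def composition(self) -> Counter:
        return Counter(self.codes)


def _resolve_termini(
    db: ChemDatabases, n_terminus: str | Terminus, c_terminus: str | Terminus
) -> tuple[Terminus, Terminus]:
    if isinstance(n_terminus, str):
        n_terminus = db.terminus(n_terminus, "N")
    if isinstance(c_terminus, str):
        c_terminus = db.terminus(c_terminus, "C")
    return n_terminus, c_terminus


def parse_peptide(
    text: str,
    n_terminus: str | Terminus = "unmodified",
    c_terminus: str | Terminus = "acid",
    db: ChemDatabases | None = None,
) -> PolymerSequence:
    """Parse a peptide string: single letters, nonstandard codes in parentheses."""
    db = db or default_databases()
    nt, ct = _resolve_termini(db, n_terminus, c_terminus)
    stripped = text.strip()
    if not stripped:
        raise SequenceParseError("empty sequence")
    residues: list[Residue] = []
    i = 0
    while i < len(stripped):
        ch = stripped[i]
        if ch == "(":
            j = stripped.find(")", i + 1)
            if j < 0:
                raise SequenceParseError("unbalanced parentheses", position=i)
            code = stripped[i + 1 : j]
            if not code:
                raise SequenceParseError("empty parentheses", position=i)
            residues.append(_lookup(db, code, PEPTIDE, position=i + 1))
            i = j + 1
        elif ch == ")":
            raise SequenceParseError("unbalanced parentheses", position=i)
        elif ch.isspace():
            raise SequenceParseError("embedded whitespace", position=i)
        else:
            residues.append(_lookup(db, ch, PEPTIDE, position=i))
            i += 1
    if len(residues) > MAX_LENGTH:
        raise SequenceLengthError(
            f"sequence length {len(residues)} exceeds the {MAX_LENGTH}-residue limit"
        )
    return PolymerSequence(tuple(residues), nt, ct)


def _lookup(db: ChemDatabases, code: str, polymer_class: str, position: int) -> Residue:
    for ch in code:
        if ch.isspace():
            raise SequenceParseError(f"whitespace inside residue code {code!r}", position=position)
    try:
        return db.residues.lookup(code, polymer_class)
    except UnknownResidueError as exc:
        raise SequenceParseError(str(exc), position=position) from None


def expand_peptoid_codes(text: str) -> list[tuple[str, int]]:
    """Expand peptoid repeat groups; returns (code, position) pairs.

    Grammar: items separated by dashes; ``( items )k`` repeats the group k
    times (k >= 1, default 1 when the multiplier is omitted); groups nest.
    Expansion is capped at MAX_LENGTH residues and aborts early, so hostile
    multipliers cannot blow up memory.
    """
    stripped = text.strip()
    if not stripped:
        raise SequenceParseError("empty sequence")

    def parse_items(pos: int, depth: int) -> tuple[list[tuple[str, int]], int]:
        items: list[tuple[str, int]] = []
        expect_item = True
        while pos < len(stripped):
            ch = stripped[pos]
            if ch == "(":
                inner, pos = parse_items(pos + 1, depth + 1)
                if pos >= len(stripped) or stripped[pos] != ")":
                    raise SequenceParseError("unbalanced parentheses", position=pos)
                pos += 1
                digits = ""
                while pos < len(stripped) and stripped[pos].isdigit():
                    digits += stripped[pos]
                    pos += 1
                mult = int(digits) if digits else 1
                if mult < 1:
                    raise SequenceParseError(
                        f"repeat multiplier must be >= 1, got {mult}", position=pos - len(digits)
                    )
                if not inner:
                    raise SequenceParseError("empty repeat group", position=pos - 1)
                if (len(items) + len(inner) * mult) > MAX_LENGTH:
                    raise SequenceLengthError(
                        f"repeat expansion exceeds the {MAX_LENGTH}-residue limit"
                    )
                items.extend(inner * mult)
                expect_item = False
            elif ch == ")":
                if depth == 0:
                    raise SequenceParseError("unbalanced parentheses", position=pos)
                break
            elif ch == "-":
                if expect_item:
                    raise SequenceParseError("dangling dash", position=pos)
                pos += 1
                expect_item = True
            elif ch.isspace():
                raise SequenceParseError("embedded whitespace", position=pos)
            else:
                start = pos
                while pos < len(stripped) and stripped[pos] not in "()-" and not stripped[pos].isspace():
                    pos += 1
                items.append((stripped[start:pos], start))
                if len(items) > MAX_LENGTH:
                    raise SequenceLengthError(
                        f"expanded sequence exceeds the {MAX_LENGTH}-residue limit"
                    )
                expect_item = False
        if expect_item and items:
            raise SequenceParseError("dangling dash", position=len(stripped) - 1)
        return items, pos

    items, pos = parse_items(0, 0)
    if pos != len(stripped):
        raise SequenceParseError("unbalanced parentheses", position=pos)
    if not items:
        raise SequenceParseError("empty sequence")
    if len(items) > MAX_LENGTH:
        raise SequenceLengthError(f"expanded sequence exceeds the {MAX_LENGTH}-residue limit")
    return items


def parse_peptoid(
    text: str,
    n_terminus: str | Terminus = "unmodified",
    c_terminus: str | Terminus = "acid",
    db: ChemDatabases | None = None,
) -> PolymerSequence:
    """Parse a dash-separated peptoid string with (nested) repeat groups."""
    db = db or default_databases()
    nt, ct = _resolve_termini(db, n_terminus, c_terminus)
    expanded = expand_peptoid_codes(text)
    residues = tuple(_lookup(db, code, PEPTOID, position=pos) for code, pos in expanded)
    return PolymerSequence(residues, nt, ct)


def canonical_string(seq: PolymerSequence) -> str:
    """Serialization that round-trips through the matching parser.

    Peptoid repeats are not re-compressed: the canonical form is the fully
    expanded dash-joined code list.
    """
    if seq.polymer_class == PEPTIDE:
        return "".join(
            r.code if (r.canonical and len(r.code) == 1) else f"({r.code})" for r in seq.residues
        )
    return "-".join(seq.codes)
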