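"""Chemical ground truth: element masses, molecular formulae, residue databases.

All masses are most-abundant-isotope (monoisotopic) masses in u.  Residue
formulae are stored *chain-incorporated* (monomer minus water); the termini
contribute the end-group atoms, so the mass of a species is a plain sum.

Constant tables ship as versioned TSV files under :mod:`pepkit.data` and can
be swapped via the ``path`` arguments of the loaders.
"""

from __future__ import annotations

import csv
import difflib
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import (
    DuplicateResidueError,
    FormulaError,
    InvalidResidueError,
    UnknownElementError,
    UnknownResidueError,
    UnknownTerminusError,
)

PEPTIDE = "peptide"
PEPTOID = "peptoid"
POLYMER_CLASSES = (PEPTIDE, PEPTOID)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pepkit").joinpath("data", name)))


def _read_tsv(path: str | Path) -> Iterator[dict[str, str]]:
    with open(path, newline="") as fh:
        rows = [r for r in fh if not r.startswith("#")]
    yield from csv.DictReader(rows, delimiter="\t")


# ---------------------------------------------------------------------------
# element masses


class ElementMassTable(Mapping[str, float]):
    """Element symbol -> most-abundant-isotope mass (u)."""

    _REQUIRED = ("H", "C", "N", "O", "S", "P", "Na", "K")

    def __init__(self, masses: Mapping[str, float]):
        self._masses = dict(masses)
        missing = [s for s in self._REQUIRED if s not in self._masses]
        if missing:
            raise ValueError(f"element mass table missing required symbols: {missing}")
        bad = {s: m for s, m in self._masses.items() if not m > 0}
        if bad:
            raise ValueError(f"non-positive element masses: {bad}")

    def __getitem__(self, symbol: str) -> float:
        try:
            return self._masses[symbol]
        except KeyError:
            raise UnknownElementError(symbol) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._masses)

    def __len__(self) -> int:
        return len(self._masses)

    @classmethod
    def from_tsv(cls, path: str | Path | None = None) -> "ElementMassTable":
        path = path or _data_path("elements.tsv")
        return cls({row["symbol"]: float(row["mass"]) for row in _read_tsv(path)})


@lru_cache(maxsize=1)
def default_masses() -> ElementMassTable:
    return ElementMassTable.from_tsv()


# ---------------------------------------------------------------------------
# formulae

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula(Mapping[str, int]):
    """Immutable element -> count map with element-wise arithmetic.

    Counts are non-negative integers; subtraction that would drive a count
    below zero raises :class:`FormulaError`.  The empty formula is the
    additive identity and has mass 0.
    """

    _counts: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        for symbol, count in self._counts:
            if not isinstance(count, int) or count < 0:
                raise FormulaError(f"invalid count for {symbol}: {count!r}")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "Formula":
        return cls(tuple(sorted((s, c) for s, c in counts.items() if c)))

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a formula string like ``C5H9NO`` (counts default to 1)."""
        text = text.strip()
        if not text:
            return cls()
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if not m:
                raise FormulaError(f"unrecognized token {text[pos]!r}", position=pos)
            symbol, digits = m.groups()
            count = int(digits) if digits else 1
            if count < 1:
                raise FormulaError(f"count for {symbol} must be >= 1", position=pos)
            counts[symbol] = counts.get(symbol, 0) + count
            pos = m.end()
        return cls.from_counts(counts)

    # -- Mapping interface
    def __getitem__(self, symbol: str) -> int:
        return dict(self._counts).get(symbol, 0)

    def __iter__(self) -> Iterator[str]:
        return (s for s, _ in self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    # -- arithmetic
    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for s, c in other.items():
            counts[s] = counts.get(s, 0) + c
        return Formula.from_counts(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for s, c in other.items():
            counts[s] = counts.get(s, 0) - c
            if counts[s] < 0:
                raise FormulaError(f"subtraction yields negative count for {s}")
        return Formula.from_counts(counts)

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula multiplier must be a non-negative integer, got {k!r}")
        return Formula.from_counts({s: c * k for s, c in self._counts})

    __rmul__ = __mul__

    def mass(self, masses: ElementMassTable | None = None) -> float:
        masses = masses or default_masses()
        return sum(c * masses[s] for s, c in self._counts)

    def hill(self) -> str:
        """Serialize in Hill order: C, H, then the rest alphabetically."""
        counts = dict(self._counts)
        symbols: list[str] = []
        if "C" in counts:
            symbols.append("C")
            if "H" in counts:
                symbols.append("H")
            symbols.extend(sorted(s for s in counts if s not in ("C", "H")))
        else:
            symbols.extend(sorted(counts))
        return "".join(f"{s}{counts[s] if counts[s] != 1 else ''}" for s in symbols)

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"


EMPTY_FORMULA = Formula()
WATER = Formula.parse("H2O")


def formula_mass(formula: Formula, masses: ElementMassTable | None = None) -> float:
    """Mass of *formula* in u under the most-abundant-isotope convention."""
    return formula.mass(masses)


def parse_formula(text: str) -> Formula:
    return Formula.parse(text)


# ---------------------------------------------------------------------------
# residues, termini, modifications


@dataclass(frozen=True)
class Residue:
    """One chain-incorporated monomer.

    ``formula`` is the dehydrated composition.  ``ionizable`` keys into the
    pKa set; ``chromophore`` is one of Trp/Tyr/Cys; ``protectable_by`` lists
    protecting-group names licensed on this residue.  ``structure_template``
    holds the side-chain graph used by the CDXML exporter (may be None).
    """

    code: str
    polymer_class: str
    formula: Formula
    canonical: bool = False
    ionizable: str | None = None
    chromophore: str | None = None
    protectable_by: tuple[str, ...] = ()
    name: str = ""
    structure_template: object | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        if self.polymer_class not in POLYMER_CLASSES:
            raise InvalidResidueError(f"invalid polymer class {self.polymer_class!r}")
        if not self.formula:
            raise InvalidResidueError(f"residue {self.code!r} has an empty formula")
        if self.canonical and self.polymer_class != PEPTIDE:
            raise InvalidResidueError("canonical residues are peptide-class by definition")

    def mass(self, masses: ElementMassTable | None = None) -> float:
        return self.formula.mass(masses)


@dataclass(frozen=True)
class Terminus:
    """Atoms appended to one chain end.  'unmodified' N + 'acid' C = chain + H2O."""

    name: str
    end: str  # "N" | "C"
    formula: Formula
    predefined: bool = True

    def __post_init__(self):
        if self.end not in ("N", "C"):
            raise ValueError(f"terminus end must be 'N' or 'C', got {self.end!r}")


N_TERMINUS_SITE = "N-terminus"


@dataclass(frozen=True)
class Modification:
    """A mass-shifting adduct: metal cation (salt form) or unremoved protecting group.

    The net composition change is ``gain - loss``; for metals loss is one H
    (cation replaces a proton).  ``sites`` restricts which residues license
    the modification; ``("*",)`` means unrestricted.
    """

    name: str
    kind: str  # "metal" | "protecting_group"
    gain: Formula
    loss: Formula = EMPTY_FORMULA
    sites: tuple[str, ...] = ("*",)
    max_per_site: int = 1

    def delta_mass(self, masses: ElementMassTable | None = None) -> float:
        return self.gain.mass(masses) - self.loss.mass(masses)

    @property
    def unrestricted(self) -> bool:
        return "*" in self.sites


# ---------------------------------------------------------------------------
# databases


class ResidueDatabase:
    """Mutable registry of residues keyed by (polymer_class, code).

    Codes are case-sensitive and unique within a polymer class.  New residues
    can be registered at run time and become immediately visible to the
    parsers and calculators.
    """

    def __init__(self, residues: Iterable[Residue] = ()):
        self._residues: dict[tuple[str, str], Residue] = {}
        for r in residues:
            self.register(r)

    def register(self, residue: Residue) -> None:
        key = (residue.polymer_class, residue.code)
        if key in self._residues:
            raise DuplicateResidueError(
                f"residue code {residue.code!r} already present in the "
                f"{residue.polymer_class} database"
            )
        self._residues[key] = residue

    def lookup(self, code: str, polymer_class: str) -> Residue:
        try:
            return self._residues[(polymer_class, code)]
        except KeyError:
            candidates = [c for pc, c in self._residues if pc == polymer_class]
            near = difflib.get_close_matches(code, candidates, n=3, cutoff=0.5)
            raise UnknownResidueError(code, polymer_class, near) from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._residues

    def residues(self, polymer_class: str) -> list[Residue]:
        return [r for (pc, _), r in self._residues.items() if pc == polymer_class]

    def codes(self, polymer_class: str) -> list[str]:
        return [c for pc, c in self._residues if pc == polymer_class]


def _load_peptide_residues(path: str | Path | None = None) -> list[Residue]:
    path = path or _data_path("residues_peptide.tsv")
    out = []
    for row in _read_tsv(path):
        out.append(
            Residue(
                code=row["code"],
                polymer_class=PEPTIDE,
                formula=Formula.parse(row["formula"]),
                canonical=row["canonical"] == "1",
                ionizable=None if row["ionizable"] == "-" else row["ionizable"],
                chromophore=None if row["chromophore"] == "-" else row["chromophore"],
                protectable_by=()
                if row["protectable"] == "-"
                else tuple(row["protectable"].split(",")),
                name=row["name"],
            )
        )
    return out


def _load_peptoid_residues(path: str | Path | None = None) -> list[Residue]:
    path = path or _data_path("residues_peptoid.tsv")
    return [
        Residue(
            code=row["code"],
            polymer_class=PEPTOID,
            formula=Formula.parse(row["formula"]),
            name=row["name"],
        )
        for row in _read_tsv(path)
    ]


def load_termini(path: str | Path | None = None) -> dict[tuple[str, str], Terminus]:
    path = path or _data_path("termini.tsv")
    return {
        (row["end"], row["name"]): Terminus(
            name=row["name"], end=row["end"], formula=Formula.parse(row["formula"])
        )
        for row in _read_tsv(path)
    }


def load_modifications(path: str | Path | None = None) -> dict[str, Modification]:
    path = path or _data_path("modifications.tsv")
    out = {}
    for row in _read_tsv(path):
        out[row["name"]] = Modification(
            name=row["name"],
            kind=row["kind"],
            gain=EMPTY_FORMULA if row["gain"] == "-" else Formula.parse(row["gain"]),
            loss=EMPTY_FORMULA if row["loss"] == "-" else Formula.parse(row["loss"]),
            sites=("*",) if row["sites"] == "*" else tuple(row["sites"].split(",")),
            max_per_site=1 if row["max_per_site"] == "-" else int(row["max_per_site"]),
        )
    return out


@dataclass
class ChemDatabases:
    """Bundle of the constant tables every calculator consumes."""

    masses: ElementMassTable
    residues: ResidueDatabase
    termini: dict[tuple[str, str], Terminus]
    modifications: dict[str, Modification]

    @classmethod
    def load(
        cls,
        elements_path: str | Path | None = None,
        peptide_path: str | Path | None = None,
        peptoid_path: str | Path | None = None,
        termini_path: str | Path | None = None,
        modifications_path: str | Path | None = None,
    ) -> "ChemDatabases":
        residues = ResidueDatabase(
            _load_peptide_residues(peptide_path) + _load_peptoid_residues(peptoid_path)
        )
        db = cls(
            masses=ElementMassTable.from_tsv(elements_path),
            residues=residues,
            termini=load_termini(termini_path),
            modifications=load_modifications(modifications_path),
        )
        db._attach_structure_templates()
        return db

    def _attach_structure_templates(self) -> None:
        from . import templates  # late import: templates has no chem dependency

        for key, residue in list(self.residues._residues.items()):
            pc, code = key
            reg = templates.PEPTIDE_SIDE_CHAINS if pc == PEPTIDE else templates.PEPTOID_SIDE_CHAINS
            if code in reg:
                self.residues._residues[key] = replace(residue, structure_template=reg[code])

    def terminus(self, spec: str, end: str) -> Terminus:
        """Resolve a terminus by predefined name (case-insensitive) or formula string.

        Custom formulae denote the atoms *added* to the bare chain end, the
        same sign convention as the predefined table.
        """
        for (e, name), term in self.termini.items():
            if e == end and name.lower() == spec.strip().lower():
                return term
        try:
            formula = Formula.parse(spec)
        except FormulaError:
            available = [name for (e, name) in self.termini if e == end]
            raise UnknownTerminusError(spec, end, available) from None
        return Terminus(name=spec.strip(), end=end, formula=formula, predefined=False)


@lru_cache(maxsize=1)
def default_databases() -> ChemDatabases:
    return ChemDatabases.load()
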