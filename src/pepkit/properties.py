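"""Molecular formula/weight, extinction coefficients, charge and isoelectric point.

Net charge follows the Henderson-Hasselbalch form: acidic groups contribute
``-1/(1+10^(pKa-pH))`` and basic groups ``+1/(1+10^(pH-pKa))``.  The pI is
the root of that (monotonically decreasing) function on [0, 14], found by
bisection.  Only the seven charged side chains plus the two free termini
carry charge terms; everything else — including nonstandard residues — is
"Other".
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping

from .chem import (
    PEPTIDE,
    ChemDatabases,
    ElementMassTable,
    Formula,
    _data_path,
    _read_tsv,
    default_databases,
)
from .errors import IsoelectricPointUndefinedError, PepkitError, UnsupportedOperationError
from .sequence import PolymerSequence

ACIDIC = -1
BASIC = +1

# groups whose charge terms Eq-style pI estimation includes
_SIDE_CHAIN_GROUPS = frozenset({"C", "D", "E", "H", "K", "R", "Y"})
_REQUIRED_GROUPS = _SIDE_CHAIN_GROUPS | {"n_term", "c_term"}
_ACIDIC_GROUPS = frozenset({"c_term", "C", "D", "E", "Y"})

# pie-summary categories (Cys and Tyr carry acidic pKa values)
ACIDIC_RESIDUES = frozenset("DECY")
BASIC_RESIDUES = frozenset("RHK")

# free-terminus names whose groups count toward charge
FREE_N_TERMINUS = "unmodified"
FREE_C_TERMINUS = "acid"


class PKaSet(Mapping[str, tuple[float, int]]):
    """group id -> (pKa, sign); sign is ACIDIC (-1) or BASIC (+1)."""

    def __init__(self, groups: Mapping[str, tuple[float, int]]):
        self._groups = dict(groups)
        if set(self._groups) != _REQUIRED_GROUPS:
            raise ValueError(
                f"pKa set must define exactly {sorted(_REQUIRED_GROUPS)}, "
                f"got {sorted(self._groups)}"
            )
        for g, (pka, sign) in self._groups.items():
            if not 0 < pka < 14:
                raise ValueError(f"pKa for {g} out of range (0, 14): {pka}")
            expected = ACIDIC if g in _ACIDIC_GROUPS else BASIC
            if sign != expected:
                raise ValueError(f"group {g} has the wrong acid/base sign")

    def __getitem__(self, group: str) -> tuple[float, int]:
        return self._groups[group]

    def __iter__(self):
        return iter(self._groups)

    def __len__(self):
        return len(self._groups)

    @classmethod
    def from_tsv(cls, path: str | Path | None = None) -> "PKaSet":
        path = path or _data_path("pka_ipc_peptide.tsv")
        groups = {}
        for row in _read_tsv(path):
            sign = ACIDIC if row["type"] == "acidic" else BASIC
            groups[row["group"]] = (float(row["pka"]), sign)
        return cls(groups)


@lru_cache(maxsize=1)
def default_pka() -> PKaSet:
    return PKaSet.from_tsv()


# ---------------------------------------------------------------------------
# formula and mass


def molecular_formula(seq: PolymerSequence) -> Formula:
    total = Formula()
    for residue in seq.residues:
        total = total + residue.formula
    return total + seq.n_terminus.formula + seq.c_terminus.formula


def molecular_weight(seq: PolymerSequence, masses: ElementMassTable | None = None) -> float:
    masses = masses or default_databases().masses
    return molecular_formula(seq).mass(masses)


# ---------------------------------------------------------------------------
# extinction coefficient (280 nm)

EPSILON_TRP = 5500
EPSILON_TYR = 1490
EPSILON_CYSTINE = 125


@dataclass(frozen=True)
class ExtinctionResult:
    n_trp: int
    n_tyr: int
    n_cys: int
    epsilon_oxidized: int  # maximum disulfide formation: n_cystine = floor(n_cys / 2)
    epsilon_reduced: int  # fully reduced: n_cystine = 0

    @property
    def n_cystine_max(self) -> int:
        return self.n_cys // 2


def extinction_280(seq: PolymerSequence) -> ExtinctionResult:
    if seq.polymer_class != PEPTIDE:
        raise UnsupportedOperationError("extinction coefficients are defined for peptides only")
    n_trp = sum(1 for r in seq.residues if r.chromophore == "Trp")
    n_tyr = sum(1 for r in seq.residues if r.chromophore == "Tyr")
    n_cys = sum(1 for r in seq.residues if r.chromophore == "Cys")
    base = EPSILON_TRP * n_trp + EPSILON_TYR * n_tyr
    return ExtinctionResult(
        n_trp=n_trp,
        n_tyr=n_tyr,
        n_cys=n_cys,
        epsilon_oxidized=base + EPSILON_CYSTINE * (n_cys // 2),
        epsilon_reduced=base,
    )


# ---------------------------------------------------------------------------
# charge summary


@dataclass(frozen=True)
class ChargeSummary:
    n_acidic: int
    n_basic: int
    n_other: int

    @property
    def total(self) -> int:
        return self.n_acidic + self.n_basic + self.n_other

    @property
    def fractions(self) -> tuple[float, float, float]:
        t = self.total
        return (self.n_acidic / t, self.n_basic / t, self.n_other / t)


def charge_summary(seq: PolymerSequence) -> ChargeSummary:
    if seq.polymer_class != PEPTIDE:
        raise UnsupportedOperationError("the charge summary is defined for peptides only")
    acidic = basic = 0
    for r in seq.residues:
        if r.canonical and r.code in ACIDIC_RESIDUES:
            acidic += 1
        elif r.canonical and r.code in BASIC_RESIDUES:
            basic += 1
    return ChargeSummary(acidic, basic, len(seq) - acidic - basic)


# ---------------------------------------------------------------------------
# net charge and isoelectric point


def ionizable_groups(seq: PolymerSequence, pka: PKaSet | None = None) -> list[tuple[float, int]]:
    """(pKa, sign) terms for *seq*: charged side chains plus free termini."""
    if seq.polymer_class != PEPTIDE:
        raise UnsupportedOperationError("charge calculations are defined for peptides only")
    pka = pka or default_pka()
    groups = [pka[r.ionizable] for r in seq.residues if r.ionizable in _SIDE_CHAIN_GROUPS]
    if seq.n_terminus.name == FREE_N_TERMINUS:
        groups.append(pka["n_term"])
    if seq.c_terminus.name == FREE_C_TERMINUS:
        groups.append(pka["c_term"])
    return groups


def charge_at(groups: list[tuple[float, int]], ph: float) -> float:
    total = 0.0
    for pk, sign in groups:
        if sign == ACIDIC:
            total += -1.0 / (1.0 + 10.0 ** (pk - ph))
        else:
            total += 1.0 / (1.0 + 10.0 ** (ph - pk))
    return total


def net_charge(seq: PolymerSequence, ph: float, pka: PKaSet | None = None) -> float:
    if not 0 <= ph <= 14:
        raise PepkitError(f"pH must lie in [0, 14], got {ph}")
    return charge_at(ionizable_groups(seq, pka), ph)


def isoelectric_point(
    seq: PolymerSequence,
    pka: PKaSet | None = None,
    tol: float = 0.001,
    charge_tol: float = 1e-6,
) -> float:
    """pH of zero net charge, located by bisection on [0, 14].

    Requires at least one acidic and one basic group; otherwise the charge
    never crosses zero and the pI is undefined.
    """
    groups = ionizable_groups(seq, pka)
    n_acid = sum(1 for _, s in groups if s == ACIDIC)
    n_base = sum(1 for _, s in groups if s == BASIC)
    if n_acid == 0 or n_base == 0:
        raise IsoelectricPointUndefinedError(
            f"pI undefined: sequence has {n_acid} acidic and {n_base} basic groups"
        )
    lo, hi = 0.0, 14.0
    if charge_at(groups, lo) <= 0 or charge_at(groups, hi) >= 0:
        raise IsoelectricPointUndefinedError("pI undefined: no sign change on [0, 14]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        c = charge_at(groups, mid)
        if abs(c) < charge_tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def charge_curve(
    seq: PolymerSequence, pka: PKaSet | None = None, step: float = 0.1
) -> list[tuple[float, float]]:
    """(pH, net charge) samples across [0, 14] for plotting/export."""
    groups = ionizable_groups(seq, pka)
    n = round(14.0 / step)
    return [(i * step, charge_at(groups, i * step)) for i in range(n + 1)]
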