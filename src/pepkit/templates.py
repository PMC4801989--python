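"""Side-chain and terminus structure templates for the CDXML exporter.

A :class:`SideChain` lists the non-backbone heavy atoms of one residue and
the bonds wiring them up.  Bond endpoints are indices into ``atoms``; two
negative sentinels refer to backbone atoms:

* ``ATTACH`` (-1): the attachment parent — the alpha carbon for peptides,
  the backbone nitrogen for peptoids (N-substituted glycines).
* ``BACKBONE_N`` (-2): the backbone nitrogen, used only for ring closures
  (proline-type residues).

Hydrogens are implicit everywhere and reconstructed from default valences.
This module is intentionally free of imports from the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass

ATTACH = -1
BACKBONE_N = -2

Bond = tuple[int, int, int]  # (a, b, order)


@dataclass(frozen=True)
class SideChain:
    atoms: tuple[str, ...]
    bonds: tuple[Bond, ...]


@dataclass(frozen=True)
class TerminusCap:
    """Atoms appended to a chain end; ATTACH = backbone N (N-cap) or carbonyl C (C-cap)."""

    atoms: tuple[str, ...]
    bonds: tuple[Bond, ...]


def _chain(elements: str | list[str], orders: list[int] | None = None) -> SideChain:
    """Linear chain attached to the parent: e.g. _chain('CCSC') for Met."""
    atoms = tuple(elements)
    orders = orders or [1] * len(atoms)
    bonds = [(ATTACH, 0, orders[0])]
    bonds += [(i, i + 1, orders[i + 1]) for i in range(len(atoms) - 1)]
    return SideChain(atoms, tuple(bonds))


def _phenyl(atoms: list[str], bonds: list[Bond], root: int) -> int:
    """Append a Kekulé benzene ring bonded to atom *root*; returns ipso index."""
    base = len(atoms)
    atoms.extend("C" * 6)
    bonds.append((root, base, 1))
    ring_orders = [2, 1, 2, 1, 2, 1]
    for k in range(6):
        bonds.append((base + k, base + (k + 1) % 6, ring_orders[k]))
    return base


def _aryl(pre: str = "C") -> SideChain:
    """-CH2- linker(s) then a phenyl ring (Phe, benzyl/phenethyl peptoids)."""
    atoms: list[str] = list(pre)
    bonds: list[Bond] = [(ATTACH, 0, 1)]
    for i in range(len(atoms) - 1):
        bonds.append((i, i + 1, 1))
    _phenyl(atoms, bonds, len(atoms) - 1)
    return SideChain(tuple(atoms), tuple(bonds))


def _tyrosine_like(phospho: bool = False) -> SideChain:
    atoms: list[str] = ["C"]
    bonds: list[Bond] = [(ATTACH, 0, 1)]
    ipso = _phenyl(atoms, bonds, 0)
    para = ipso + 3
    oh = len(atoms)
    atoms.append("O")
    bonds.append((para, oh, 1))
    if phospho:
        p = len(atoms)
        atoms.extend(["P", "O", "O", "O"])
        bonds += [(oh, p, 1), (p, p + 1, 2), (p, p + 2, 1), (p, p + 3, 1)]
    return SideChain(tuple(atoms), tuple(bonds))


def _phospho(pre: str) -> SideChain:
    """-O-PO(OH)2 on the last atom of a carbon scaffold (pSer, pThr)."""
    sc = _chain(pre)
    atoms = list(sc.atoms)
    bonds = list(sc.bonds)
    og = len(atoms) - 1  # terminal O of the scaffold
    p = len(atoms)
    atoms.extend(["P", "O", "O", "O"])
    bonds += [(og, p, 1), (p, p + 1, 2), (p, p + 2, 1), (p, p + 3, 1)]
    return SideChain(tuple(atoms), tuple(bonds))


_TRP = SideChain(
    # CB, CG, CD1, NE1, CE2, CD2, CE3, CZ3, CH2, CZ2
    atoms=("C", "C", "C", "N", "C", "C", "C", "C", "C", "C"),
    bonds=(
        (ATTACH, 0, 1),
        (0, 1, 1),
        (1, 2, 2),
        (2, 3, 1),
        (3, 4, 1),
        (4, 5, 1),
        (5, 1, 1),
        (5, 6, 2),
        (6, 7, 1),
        (7, 8, 2),
        (8, 9, 1),
        (9, 4, 2),
    ),
)

_HIS = SideChain(
    # CB, CG, ND1, CE1, NE2, CD2
    atoms=("C", "C", "N", "C", "N", "C"),
    bonds=(
        (ATTACH, 0, 1),
        (0, 1, 1),
        (1, 2, 1),
        (2, 3, 2),
        (3, 4, 1),
        (4, 5, 1),
        (5, 1, 2),
    ),
)

_ARG = SideChain(
    # CB, CG, CD, NE, CZ, NH1(=), NH2
    atoms=("C", "C", "C", "N", "C", "N", "N"),
    bonds=(
        (ATTACH, 0, 1),
        (0, 1, 1),
        (1, 2, 1),
        (2, 3, 1),
        (3, 4, 1),
        (4, 5, 2),
        (4, 6, 1),
    ),
)

_PRO = SideChain(
    atoms=("C", "C", "C"),
    bonds=((ATTACH, 0, 1), (0, 1, 1), (1, 2, 1), (2, BACKBONE_N, 1)),
)

_HYP = SideChain(
    atoms=("C", "C", "C", "O"),
    bonds=((ATTACH, 0, 1), (0, 1, 1), (1, 2, 1), (2, BACKBONE_N, 1), (1, 3, 1)),
)


def _carboxamide(n_carbons: int, terminal: str) -> SideChain:
    """-(CH2)n-C(=O)X with X = O (acid) or N (amide)."""
    atoms = tuple("C" * n_carbons) + ("C", "O", terminal)
    bonds: list[Bond] = [(ATTACH, 0, 1)]
    for i in range(n_carbons):
        bonds.append((i, i + 1, 1))
    cz = n_carbons
    bonds += [(cz, cz + 1, 2), (cz, cz + 2, 1)]
    return SideChain(atoms, tuple(bonds))


PEPTIDE_SIDE_CHAINS: dict[str, SideChain] = {
    "G": SideChain((), ()),
    "A": _chain("C"),
    "V": SideChain(("C", "C", "C"), ((ATTACH, 0, 1), (0, 1, 1), (0, 2, 1))),
    "L": SideChain(("C", "C", "C", "C"), ((ATTACH, 0, 1), (0, 1, 1), (1, 2, 1), (1, 3, 1))),
    "I": SideChain(("C", "C", "C", "C"), ((ATTACH, 0, 1), (0, 1, 1), (0, 2, 1), (1, 3, 1))),
    "S": _chain("CO"),
    "T": SideChain(("C", "O", "C"), ((ATTACH, 0, 1), (0, 1, 1), (0, 2, 1))),
    "C": _chain("CS"),
    "M": _chain("CCSC"),
    "D": _carboxamide(1, "O"),
    "E": _carboxamide(2, "O"),
    "N": _carboxamide(1, "N"),
    "Q": _carboxamide(2, "N"),
    "K": _chain("CCCCN"),
    "R": _ARG,
    "H": _HIS,
    "F": _aryl("C"),
    "Y": _tyrosine_like(),
    "W": _TRP,
    "P": _PRO,
    "pS": _phospho("CO"),
    "pT": SideChain(
        ("C", "O", "C", "P", "O", "O", "O"),
        (
            (ATTACH, 0, 1),
            (0, 1, 1),
            (0, 2, 1),
            (1, 3, 1),
            (3, 4, 2),
            (3, 5, 1),
            (3, 6, 1),
        ),
    ),
    "pY": _tyrosine_like(phospho=True),
    "Hyp": _HYP,
    "Nle": _chain("CCCC"),
    "Orn": _chain("CCCN"),
    "Cit": SideChain(
        ("C", "C", "C", "N", "C", "O", "N"),
        (
            (ATTACH, 0, 1),
            (0, 1, 1),
            (1, 2, 1),
            (2, 3, 1),
            (3, 4, 1),
            (4, 5, 2),
            (4, 6, 1),
        ),
    ),
    "Aib": SideChain(("C", "C"), ((ATTACH, 0, 1), (ATTACH, 1, 1))),
}

PEPTOID_SIDE_CHAINS: dict[str, SideChain] = {
    "Nme": _chain("C"),
    "Nab": _chain("CCCCN"),
    "Nlys": _chain("CCCCN"),
    "Nae": _chain("CCN"),
    "Npe": _aryl("CC"),
    "Nspe": SideChain(
        tuple(["C", "C"] + ["C"] * 6),
        (
            (ATTACH, 0, 1),
            (0, 1, 1),
            (0, 2, 1),
            (2, 3, 2),
            (3, 4, 1),
            (4, 5, 2),
            (5, 6, 1),
            (6, 7, 2),
            (7, 2, 1),
        ),
    ),
    "Npm": _aryl("C"),
    "Nib": SideChain(("C", "C", "C", "C"), ((ATTACH, 0, 1), (0, 1, 1), (1, 2, 1), (1, 3, 1))),
    "Nbu": _chain("CCCC"),
    "Nce": _carboxamide(2, "O"),
    "Nhe": _chain("CCO"),
}
PEPTOID_SIDE_CHAINS["Nrpe"] = PEPTOID_SIDE_CHAINS["Nspe"]

# Terminus caps.  N caps bond to the backbone nitrogen of residue 1; C caps
# bond to the carbonyl carbon of the last residue.  The free amine
# ('unmodified') adds no heavy atoms — implicit hydrogens complete NH2.
N_TERMINUS_CAPS: dict[str, TerminusCap] = {
    "unmodified": TerminusCap((), ()),
    "acetyl": TerminusCap(("C", "C", "O"), ((ATTACH, 0, 1), (0, 1, 1), (0, 2, 2))),
    "formyl": TerminusCap(("C", "O"), ((ATTACH, 0, 1), (0, 1, 2))),
    "boc": TerminusCap(
        ("C", "O", "O", "C", "C", "C", "C"),
        (
            (ATTACH, 0, 1),
            (0, 1, 2),
            (0, 2, 1),
            (2, 3, 1),
            (3, 4, 1),
            (3, 5, 1),
            (3, 6, 1),
        ),
    ),
}

C_TERMINUS_CAPS: dict[str, TerminusCap] = {
    "acid": TerminusCap(("O",), ((ATTACH, 0, 1),)),
    "amide": TerminusCap(("N",), ((ATTACH, 0, 1),)),
    "methyl ester": TerminusCap(("O", "C"), ((ATTACH, 0, 1), (0, 1, 1))),
    "ethyl 3-mercaptopropionate thioester": TerminusCap(
        ("S", "C", "C", "C", "O", "O", "C", "C"),
        (
            (ATTACH, 0, 1),
            (0, 1, 1),
            (1, 2, 1),
            (2, 3, 1),
            (3, 4, 2),
            (3, 5, 1),
            (5, 6, 1),
            (6, 7, 1),
        ),
    ),
}
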