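"""All-atom structure assembly and ChemDraw CDXML export.

The structure graph is functional rather than aesthetic: the backbone is laid
out on a zig-zag, side chains grow perpendicular to it, and hydrogens are
implicit (reconstructed from default valences).  Output is deterministic —
fixed id numbering, no timestamps — so files are diff-stable.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from . import templates
from .chem import PEPTIDE, Formula
from .errors import PepkitError, StructureUnavailableError
from .sequence import PolymerSequence

BOND_LENGTH = 30.0  # CDXML layout units

DEFAULT_VALENCE = {
    "H": 1,
    "C": 4,
    "N": 3,
    "O": 2,
    "S": 2,
    "P": 5,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
    "Se": 2,
}

ATOMIC_NUMBER = {
    "H": 1,
    "C": 6,
    "N": 7,
    "O": 8,
    "F": 9,
    "Na": 11,
    "P": 15,
    "S": 16,
    "Cl": 17,
    "K": 19,
    "Se": 34,
    "Br": 35,
    "I": 53,
}


@dataclass(frozen=True)
class Atom:
    element: str
    x: float
    y: float


@dataclass(frozen=True)
class GraphBond:
    a: int
    b: int
    order: int


@dataclass
class StructureGraph:
    """Heavy-atom graph with 2-D coordinates and implicit hydrogens."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[GraphBond] = field(default_factory=list)

    def add_atom(self, element: str, x: float, y: float) -> int:
        self.atoms.append(Atom(element, x, y))
        return len(self.atoms) - 1

    def add_bond(self, a: int, b: int, order: int = 1) -> None:
        if order not in (1, 2):
            raise ValueError(f"bond order must be 1 or 2, got {order}")
        self.bonds.append(GraphBond(a, b, order))

    def implicit_hydrogens(self) -> list[int]:
        used = [0] * len(self.atoms)
        for bond in self.bonds:
            used[bond.a] += bond.order
            used[bond.b] += bond.order
        out = []
        for i, atom in enumerate(self.atoms):
            valence = DEFAULT_VALENCE.get(atom.element)
            if valence is None:
                raise PepkitError(f"no default valence for element {atom.element!r}")
            h = valence - used[i]
            if h < 0:
                raise PepkitError(
                    f"atom {i} ({atom.element}) exceeds valence {valence} "
                    f"with {used[i]} bond orders"
                )
            out.append(h)
        return out

    def formula(self) -> Formula:
        """Element counts of the molecule: heavy atoms plus implicit H."""
        counts: dict[str, int] = {}
        for atom in self.atoms:
            counts[atom.element] = counts.get(atom.element, 0) + 1
        counts["H"] = counts.get("H", 0) + sum(self.implicit_hydrogens())
        return Formula.from_counts(counts)

    def is_connected(self) -> bool:
        if not self.atoms:
            return False
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
        for bond in self.bonds:
            adj[bond.a].append(bond.b)
            adj[bond.b].append(bond.a)
        seen = {0}
        stack = [0]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == len(self.atoms)


def _place_template(
    graph: StructureGraph,
    atoms: tuple[str, ...],
    bonds: tuple[templates.Bond, ...],
    anchors: dict[int, int],
    origin: tuple[float, float],
    direction: tuple[float, float],
) -> None:
    """Add template atoms/bonds to *graph*, growing from *origin* along *direction*.

    *anchors* maps negative template sentinels to graph atom indices.  Atom
    positions follow breadth-first depth from the anchors with a small
    per-sibling lateral offset; layout only needs to be deterministic.
    """
    if not atoms:
        return
    # BFS depth of each template atom from any anchor
    adj: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    roots: list[int] = []
    for a, b, _ in bonds:
        if a < 0 and b >= 0:
            roots.append(b)
        elif b < 0 and a >= 0:
            roots.append(a)
        elif a >= 0 and b >= 0:
            adj[a].append(b)
            adj[b].append(a)
    depth = {r: 1 for r in roots}
    queue = list(dict.fromkeys(roots))
    while queue:
        i = queue.pop(0)
        for j in adj[i]:
            if j not in depth:
                depth[j] = depth[i] + 1
                queue.append(j)
    lateral = (-direction[1], direction[0])
    seen_at_depth: dict[int, int] = {}
    index: dict[int, int] = {}
    for t in range(len(atoms)):
        d = depth.get(t, 1)
        k = seen_at_depth.get(d, 0)
        seen_at_depth[d] = k + 1
        off = 0.45 * BOND_LENGTH * k
        x = origin[0] + direction[0] * BOND_LENGTH * d + lateral[0] * off
        y = origin[1] + direction[1] * BOND_LENGTH * d + lateral[1] * off
        index[t] = graph.add_atom(atoms[t], x, y)
    for a, b, order in bonds:
        ga = anchors[a] if a < 0 else index[a]
        gb = anchors[b] if b < 0 else index[b]
        graph.add_bond(ga, gb, order)


def build_structure(seq: PolymerSequence) -> StructureGraph:
    """Assemble the all-atom heavy graph for *seq*.

    Residue templates are chained through amide backbone bonds (tertiary
    amides for peptoids, whose side chains hang off the backbone nitrogen)
    and capped with the terminus templates.  Raises
    :class:`StructureUnavailableError` for residues or custom termini
    without a template.
    """
    is_peptide = seq.polymer_class == PEPTIDE
    n_caps = templates.N_TERMINUS_CAPS
    c_caps = templates.C_TERMINUS_CAPS
    if seq.n_terminus.name not in n_caps:
        raise StructureUnavailableError(f"N-terminus {seq.n_terminus.name}")
    if seq.c_terminus.name not in c_caps:
        raise StructureUnavailableError(f"C-terminus {seq.c_terminus.name}")

    graph = StructureGraph()
    dx = BOND_LENGTH * 0.866
    dy = BOND_LENGTH * 0.25
    prev_carbonyl: int | None = None
    first_n: int | None = None
    t = 0  # backbone atom counter for the zig-zag

    for i, residue in enumerate(seq.residues):
        template: templates.SideChain | None = residue.structure_template  # type: ignore[assignment]
        if template is None:
            raise StructureUnavailableError(residue.code)
        pos = []
        for _ in range(3):  # N, CA, C'
            pos.append((t * dx, dy if t % 2 else -dy))
            t += 1
        n = graph.add_atom("N", *pos[0])
        ca = graph.add_atom("C", *pos[1])
        c = graph.add_atom("C", *pos[2])
        o = graph.add_atom("O", pos[2][0], pos[2][1] - BOND_LENGTH)
        graph.add_bond(n, ca)
        graph.add_bond(ca, c)
        graph.add_bond(c, o, 2)
        if prev_carbonyl is not None:
            graph.add_bond(prev_carbonyl, n)
        if first_n is None:
            first_n = n
        attach = ca if is_peptide else n
        attach_pos = pos[1] if is_peptide else pos[0]
        _place_template(
            graph,
            template.atoms,
            template.bonds,
            anchors={templates.ATTACH: attach, templates.BACKBONE_N: n},
            origin=attach_pos,
            direction=(0.0, 1.0),
        )
        prev_carbonyl = c

    assert first_n is not None and prev_carbonyl is not None
    ncap = n_caps[seq.n_terminus.name]
    _place_template(
        graph,
        ncap.atoms,
        ncap.bonds,
        anchors={templates.ATTACH: first_n},
        origin=(graph.atoms[first_n].x, graph.atoms[first_n].y),
        direction=(-0.866, -0.5),
    )
    ccap = c_caps[seq.c_terminus.name]
    _place_template(
        graph,
        ccap.atoms,
        ccap.bonds,
        anchors={templates.ATTACH: prev_carbonyl},
        origin=(graph.atoms[prev_carbonyl].x, graph.atoms[prev_carbonyl].y),
        direction=(0.866, 0.5),
    )
    return graph


def write_cdxml(graph: StructureGraph) -> str:
    """Serialize *graph* as CDXML text (one fragment, deterministic ids)."""
    if not graph.atoms:
        raise PepkitError("refusing to write an empty structure")
    root = ET.Element("CDXML", {"BondLength": f"{BOND_LENGTH:g}"})
    page = ET.SubElement(root, "page", {"id": "1"})
    fragment = ET.SubElement(page, "fragment", {"id": "2"})
    base = 10
    for i, atom in enumerate(graph.atoms):
        attrs = {"id": str(base + i), "p": f"{atom.x:.2f} {atom.y:.2f}"}
        if atom.element != "C":
            attrs["Element"] = str(ATOMIC_NUMBER[atom.element])
        ET.SubElement(fragment, "n", attrs)
    bond_base = base + len(graph.atoms)
    for k, bond in enumerate(graph.bonds):
        ET.SubElement(
            fragment,
            "b",
            {
                "id": str(bond_base + k),
                "B": str(base + bond.a),
                "E": str(base + bond.b),
                "Order": str(bond.order),
            },
        )
    ET.indent(root)
    body = ET.tostring(root, encoding="unicode")
    return (
        '<?xml version="1.0" encoding="UTF-8" ?>\n'
        '<!DOCTYPE CDXML SYSTEM "http://www.cambridgesoft.com/xml/cdxml.dtd" >\n'
        + body
        + "\n"
    )


def sequence_to_cdxml(seq: PolymerSequence) -> str:
    return write_cdxml(build_structure(seq))
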