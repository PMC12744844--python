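"""Steric extent of 2'-ribose modifications.

The size of a 2'-ribose substituent is measured as the distance from the
ribose C2' carbon to the farthest atom of the substituent (hydrogens
included — for a 2'-deoxy residue the substituent *is* the 2' hydrogens).
Coordinate files carry no connectivity, so bonds are inferred from summed
covalent radii, and the substituent is collected by graph traversal from C2'
that is forbidden from re-entering the ring through C1' or C3'.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass

import numpy as np

from .errors import SirmsdError, TopologyError, UnknownElementError
from .structures import Atom, Residue

#: Single-bond covalent radii (Å), Cordero et al. consensus values.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "D": 0.31, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "P": 1.07, "S": 1.05, "CL": 1.02, "BR": 1.20,
}

#: Default slack added to summed covalent radii when inferring bonds.
BOND_TOLERANCE = 0.45

_RIBOSE_RING = ("C1'", "C2'", "C3'", "C4'", "O4'")
_BACKBONE = {"P", "OP1", "OP2", "OP3", "O5'", "C5'", "O3'"}


def _radius(atom: Atom) -> float:
    key = atom.element.upper()
    if key not in COVALENT_RADII:
        raise UnknownElementError(
            f"no covalent radius tabulated for element {atom.element!r} "
            f"(atom {atom.name})")
    return COVALENT_RADII[key]


def infer_bonds(residue: Residue, tolerance: float = BOND_TOLERANCE) -> list[tuple[str, str]]:
    """Infer covalent bonds: i–j bonded iff d(i,j) < r_cov(i)+r_cov(j)+tolerance.

    Returns name pairs with each pair ordered alphabetically, sorted; the
    relation is symmetric and has no self-bonds.
    """
    bonds = []
    for a, b in itertools.combinations(residue.atoms, 2):
        cutoff = _radius(a) + _radius(b) + tolerance
        if float(np.linalg.norm(a.coords - b.coords)) < cutoff:
            bonds.append(tuple(sorted((a.name, b.name))))
    return sorted(set(bonds))


@dataclass
class SubstituentSet:
    """The 2' substituent: anchor C2' plus every atom hanging off it."""

    anchor: Atom
    atoms: list[Atom]


@dataclass
class ModificationExtent:
    """Distance from C2' to the farthest substituent atom."""

    modification: str
    extent: float  # Å
    farthest_atom: str


def substituent_atoms(residue: Residue, tolerance: float = BOND_TOLERANCE) -> SubstituentSet:
    """Collect the 2' substituent by breadth-first traversal from C2'.

    C1' and C3' (and everything reachable only through them) are excluded.
    The substituent is the non-hydrogen branch hanging off C2' (with every
    atom downstream of it, hydrogens included); when C2' carries no heavy
    substituent — a 2'-deoxy residue — its geminal hydrogens *are* the
    substituent.  Reaching the phosphate backbone means the inferred bond
    graph short-circuited the ring and is reported as a topology error.
    """
    if not residue.has_atom("C2'"):
        raise SirmsdError(
            f"residue {residue.guide_position}: no C2' atom; cannot locate "
            "the 2' substituent")
    bonds = infer_bonds(residue, tolerance)
    adjacency: dict[str, set[str]] = {}
    for i, j in bonds:
        adjacency.setdefault(i, set()).add(j)
        adjacency.setdefault(j, set()).add(i)

    blocked = {"C1'", "C3'"}
    neighbors = adjacency.get("C2'", set()) - blocked
    heavy_roots = {n for n in neighbors if not residue.atom(n).is_hydrogen}
    roots = heavy_roots if heavy_roots else neighbors
    visited = {"C2'"} | blocked | (neighbors - roots)
    queue = deque(roots)
    members: list[str] = []
    while queue:
        name = queue.popleft()
        if name in visited:
            continue
        visited.add(name)
        if name in _BACKBONE or name in _RIBOSE_RING:
            raise TopologyError(
                f"residue {residue.guide_position}: traversal from C2' "
                f"reached {name}; the inferred bond graph bridges the "
                "substituent to the ring/backbone (tolerance too large?)")
        members.append(name)
        queue.extend(adjacency.get(name, set()) - visited)
    return SubstituentSet(residue.atom("C2'"), [residue.atom(n) for n in members])


def modification_extent(residue: Residue, tolerance: float = BOND_TOLERANCE) -> ModificationExtent:
    """Max distance from C2' to any substituent atom, with the atom's name."""
    sub = substituent_atoms(residue, tolerance)
    if not sub.atoms:
        raise SirmsdError(
            f"residue {residue.guide_position}: empty 2' substituent")
    anchor = sub.anchor.coords
    best_atom, best_dist = None, -1.0
    for atom in sub.atoms:
        d = float(np.linalg.norm(atom.coords - anchor))
        if d > best_dist:
            best_atom, best_dist = atom, d
    return ModificationExtent(residue.modification, best_dist, best_atom.name)
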