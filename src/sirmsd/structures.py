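"""Structure models for siRNA guide-strand fragments.

Coordinates of a chemically modified guide-RNA fragment and its unmodified
counterpart, both posed in the same AGO2-bound reference frame, are the raw
input of the siRMSD statistic.  This module reads those coordinates
(fixed-column PDB records, or bare element/x/y/z blocks accompanied by an
atom-annotation table), indexes atoms by 1-based guide position, selects the
nucleobase heavy atoms that enter the statistic, and pairs equivalent atoms
between the two models.

Conventions
-----------
* Guide positions are 1-based from the 5' end of the guide strand and are
  taken from the PDB residue sequence number.
* Atom names are normalized: whitespace stripped, ``*`` unified to ``'``
  (legacy PDB dialect), and the thymine methyl ``C5M`` unified to ``C7``.
* Alternate locations are resolved by highest occupancy; ties break to the
  lexicographically smallest alt-loc code.
* Insertion codes are rejected rather than guessed — silently misindexing a
  residue would corrupt the per-position statistic.
* Hydrogens are kept at parse time (the sterics module needs them); they are
  identified by element H or D, never by name heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    AnnotationError,
    IncompleteResidueError,
    PairingError,
    PdbParseError,
    UnsupportedFeatureError,
)

BASES = ("A", "U", "G", "C", "T")

#: Closed vocabulary of 2'-ribose chemistries handled by this package.
MODIFICATIONS = ("RNA", "DNA", "FLUORO", "MOE", "OME", "FA", "MTMM")

#: Nucleobase heavy atoms (ring plus exocyclic substituents; no sugar, no
#: phosphate, no hydrogens), in canonical name order.  Thymine carries the
#: exocyclic methyl carbon, canonically named C7 (PDB v3; legacy C5M).
NUCLEOBASE_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "C2", "N3", "C4", "C5", "C6", "N6", "N7", "C8", "N9"),
    "G": ("N1", "C2", "N2", "N3", "C4", "C5", "C6", "O6", "N7", "C8", "N9"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
    "T": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6", "C7"),
}

# Residue-name convention: unmodified RNA uses the bare base letter, DNA the
# PDB two-letter codes, 2'-OMe the standard OMx chemical-component codes, and
# the remaining chemistries this package's own three-letter codes (base
# letter + two-letter chemistry tag).  Synthetic files written by the
# fixtures module use the same table.
_RESNAME_OF: dict[tuple[str, str], str] = {}
_PARSE_RESNAME: dict[str, tuple[str, str]] = {}


def _register(base: str, modification: str, resname: str) -> None:
    _RESNAME_OF[(base, modification)] = resname
    _PARSE_RESNAME[resname] = (base, modification)


for _b in BASES:
    _register(_b, "RNA", _b)
    _register(_b, "DNA", f"D{_b}")
    _register(_b, "OME", f"OM{_b}")
    _register(_b, "FLUORO", f"{_b}FL")
    _register(_b, "MOE", f"{_b}MO")
    _register(_b, "FA", f"{_b}FA")
    _register(_b, "MTMM", f"{_b}MT")

_TWO_LETTER_ELEMENTS = {"CL", "BR", "SE", "MG", "ZN", "FE", "MN", "NA"}


def normalize_atom_name(name: str) -> str:
    """Strip whitespace, unify ``*`` to ``'`` and legacy C5M to C7."""
    name = name.strip().upper().replace("*", "'")
    if name == "C5M":
        return "C7"
    return name


def element_from_name(name: str) -> str:
    """Infer the element symbol implied by a (normalized) atom name."""
    stripped = "".join(ch for ch in normalize_atom_name(name) if ch.isalpha())
    if not stripped:
        raise AnnotationError(f"atom name {name!r} implies no element")
    if stripped[:2] in _TWO_LETTER_ELEMENTS:
        return stripped[:2].capitalize()
    return stripped[0]


@dataclass(frozen=True)
class Atom:
    """A single atom: name, element, Cartesian coordinates in angstroms."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def translated(self, shift: np.ndarray) -> "Atom":
        return Atom(self.serial, self.name, self.element,
                    self.coords + np.asarray(shift, dtype=float),
                    self.occupancy, self.alt_loc)


@dataclass
class Residue:
    """One nucleotide of the guide strand.

    ``guide_position`` is 1-based from the 5' end; ``modification`` names the
    2'-ribose chemistry.
    """

    guide_position: int
    base: str
    modification: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.guide_position < 1:
            raise ValueError("guide_position must be >= 1")
        if self.base not in BASES:
            raise ValueError(f"unknown base {self.base!r}")
        if self.modification not in MODIFICATIONS:
            raise ValueError(f"unknown modification {self.modification!r}")

    def atom(self, name: str) -> Atom:
        name = normalize_atom_name(name)
        for atom in self.atoms:
            if atom.name == name:
                return atom
        raise KeyError(name)

    def has_atom(self, name: str) -> bool:
        try:
            self.atom(name)
            return True
        except KeyError:
            return False


@dataclass
class StructureModel:
    """An ordered set of guide-strand residues in one coordinate frame."""

    model_id: str
    residues: list[Residue]
    source: str = "SYNTHETIC"  # PDB | XYZ_ANNOTATED | SYNTHETIC

    def __post_init__(self) -> None:
        self.residues = sorted(self.residues, key=lambda r: r.guide_position)
        seen_pos: set[int] = set()
        for res in self.residues:
            if res.guide_position in seen_pos:
                raise ValueError(f"duplicate guide position {res.guide_position}")
            seen_pos.add(res.guide_position)
            names = [a.name for a in res.atoms]
            if len(names) != len(set(names)):
                dupes = sorted({n for n in names if names.count(n) > 1})
                raise ValueError(
                    f"residue {res.guide_position}: duplicate atom names {dupes}")

    @property
    def positions(self) -> list[int]:
        return [r.guide_position for r in self.residues]

    def residue(self, guide_position: int) -> Residue:
        for res in self.residues:
            if res.guide_position == guide_position:
                return res
        raise KeyError(guide_position)

    def has_position(self, guide_position: int) -> bool:
        return guide_position in self.positions

    def translated(self, shift) -> "StructureModel":
        shift = np.asarray(shift, dtype=float)
        return StructureModel(
            self.model_id,
            [Residue(r.guide_position, r.base, r.modification,
                     [a.translated(shift) for a in r.atoms])
             for r in self.residues],
            self.source,
        )

    def to_tsv(self) -> str:
        """Dump as TSV (guide_position, atom_name, element, x, y, z)."""
        lines = ["guide_position\tatom_name\telement\tx\ty\tz"]
        for res in self.residues:
            for a in res.atoms:
                x, y, z = a.coords
                lines.append(
                    f"{res.guide_position}\t{a.name}\t{a.element}\t{x:.6g}\t{y:.6g}\t{z:.6g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB fixed-column reading/writing
# ---------------------------------------------------------------------------

def _parse_pdb_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16]
        alt_loc = line[16].strip()
        resname = line[17:20].strip()
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"line {lineno}: malformed fixed-column record: {exc}") from exc
    if icode:
        raise UnsupportedFeatureError(
            f"line {lineno}: insertion code {icode!r} is not supported; "
            "renumber residues instead")
    name = normalize_atom_name(name)
    if not element:
        element = element_from_name(name)
    return serial, name, alt_loc, resname, resseq, (x, y, z), occupancy, element.capitalize()


def read_pdb(text: str, model_id: str = "pdb") -> StructureModel:
    """Read ATOM/HETATM records from fixed-column PDB content.

    Alt-loc conflicts keep the highest-occupancy copy (ties break to the
    smallest alt-loc code); hydrogens are retained.  Residues are indexed by
    residue sequence number, interpreted as the 1-based guide position.
    """
    # (resseq) -> (resname, {atom name -> chosen record})
    residues: dict[int, tuple[str, dict[str, tuple]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line[:6].rstrip() in ("ATOM", "HETATM"):
            continue
        rec = _parse_pdb_atom_line(line, lineno)
        serial, name, alt_loc, resname, resseq, xyz, occ, element = rec
        if resseq not in residues:
            residues[resseq] = (resname, {})
        stored_name, atoms = residues[resseq]
        if stored_name != resname:
            raise PdbParseError(
                f"line {lineno}: residue {resseq} has conflicting names "
                f"{stored_name!r} and {resname!r}")
        if name in atoms:
            prev = atoms[name]
            # keep highest occupancy; tie -> lexicographically smallest alt_loc
            if occ > prev[5] or (occ == prev[5] and _altkey(alt_loc) < _altkey(prev[4])):
                atoms[name] = (serial, name, element, xyz, alt_loc, occ)
        else:
            atoms[name] = (serial, name, element, xyz, alt_loc, occ)

    out: list[Residue] = []
    for resseq in sorted(residues):
        resname, atoms = residues[resseq]
        if resname not in _PARSE_RESNAME:
            raise PdbParseError(
                f"residue {resseq}: unknown residue name {resname!r} "
                f"(known: base letters, D?, OM?, ?FL/?MO/?FA/?MT codes)")
        base, modification = _PARSE_RESNAME[resname]
        res_atoms = [Atom(serial, name, element, np.array(xyz), occ, alt_loc)
                     for serial, name, element, xyz, alt_loc, occ
                     in sorted(atoms.values(), key=lambda t: t[0])]
        out.append(Residue(resseq, base, modification, res_atoms))
    return StructureModel(model_id, out, source="PDB")


def _altkey(alt_loc: str) -> str:
    # empty alt-loc sorts before any letter (it is the unambiguous copy)
    return alt_loc if alt_loc else ""


def write_pdb(model: StructureModel) -> str:
    """Render a model as fixed-column PDB ATOM records (plus END)."""
    lines = []
    serial = 0
    for res in model.residues:
        resname = _RESNAME_OF[(res.base, res.modification)]
        for atom in res.atoms:
            serial += 1
            name = atom.name
            # PDB name field: element right-justified in cols 13-14 for
            # single-letter elements -> pad with a leading space if short.
            field4 = name if len(name) >= 4 else f" {name:<3s}"
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d} {field4}{'':1s}{resname:>3s} A{res.guide_position:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element.upper():>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Annotated XYZ reading
# ---------------------------------------------------------------------------

def read_annotated_xyz(coords: str, atom_map: str, model_id: str = "xyz") -> StructureModel:
    """Assemble a model from an element/x/y/z block plus an annotation table.

    Coordinate listings deposited with quantum-chemistry outputs carry no
    residue labels; ``atom_map`` is a TSV with header columns
    ``guide_position``, ``base``, ``modification``, ``atom_name`` assigning
    each coordinate row (in order) to a residue and atom.  The element of
    each coordinate row must agree with the element implied by the mapped
    atom name.
    """
    coord_rows: list[tuple[str, float, float, float]] = []
    for lineno, line in enumerate(coords.splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 4:
            raise AnnotationError(
                f"coords row {lineno}: expected 'element x y z', got {line!r}")
        try:
            coord_rows.append((parts[0].capitalize(),
                               float(parts[1]), float(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise AnnotationError(f"coords row {lineno}: {exc}") from exc

    map_rows: list[tuple[int, str, str, str]] = []
    lines = [ln for ln in atom_map.splitlines() if ln.strip()]
    if not lines:
        raise AnnotationError("empty atom map")
    header = [h.strip() for h in lines[0].split("\t")]
    required = ["guide_position", "base", "modification", "atom_name"]
    if header[: len(required)] != required:
        raise AnnotationError(
            f"atom map header must start with {required}, got {header}")
    for lineno, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 4:
            raise AnnotationError(f"atom map row {lineno}: expected 4 columns")
        map_rows.append((int(parts[0]), parts[1].upper(), parts[2].upper(),
                         normalize_atom_name(parts[3])))

    if len(coord_rows) != len(map_rows):
        raise AnnotationError(
            f"row-count mismatch: {len(coord_rows)} coordinate rows vs "
            f"{len(map_rows)} map rows")

    residues: dict[int, Residue] = {}
    for i, ((element, x, y, z), (pos, base, modification, name)) in enumerate(
            zip(coord_rows, map_rows), start=1):
        implied = element_from_name(name)
        if element.upper() != implied.upper():
            raise AnnotationError(
                f"row {i}: atom name {name!r} implies element {implied}, "
                f"coordinate row says {element}")
        if pos not in residues:
            residues[pos] = Residue(pos, base, modification, [])
        res = residues[pos]
        if (res.base, res.modification) != (base, modification):
            raise AnnotationError(
                f"row {i}: residue {pos} annotated inconsistently")
        res.atoms.append(Atom(i, name, element, np.array([x, y, z])))
    return StructureModel(model_id, list(residues.values()), source="XYZ_ANNOTATED")


# ---------------------------------------------------------------------------
# Selections and pairing
# ---------------------------------------------------------------------------

def nucleobase_heavy_atoms(residue: Residue) -> list[Atom]:
    """Base-specific heavy atoms of the nucleobase, in canonical order.

    Sugar and phosphate atoms are excluded, as are hydrogens; a missing base
    atom raises :class:`IncompleteResidueError` listing all missing names.
    """
    names = NUCLEOBASE_HEAVY_ATOMS[residue.base]
    missing = [n for n in names if not residue.has_atom(n)]
    if missing:
        raise IncompleteResidueError(
            f"residue {residue.guide_position} ({residue.base}): "
            f"missing nucleobase atoms {missing}")
    return [residue.atom(n) for n in names]


@dataclass
class AtomPairing:
    """Matched atoms of two models with their Euclidean separations δ (Å)."""

    pairs: list[tuple[Atom, Atom, float]]

    @property
    def K(self) -> int:
        return len(self.pairs)

    @property
    def deltas(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs], dtype=float)


def _kabsch_transform(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``target`` (Kabsch)."""
    from scipy.spatial.transform import Rotation

    mob_c = mobile - mobile.mean(axis=0)
    tgt_c = target - target.mean(axis=0)
    rot, _ = Rotation.align_vectors(tgt_c, mob_c)
    return rot.apply(mob_c) + target.mean(axis=0)


def pair_by_name(
    modified: StructureModel,
    unmodified: StructureModel,
    selection: Mapping[int, Sequence[str]],
    superpose: bool = False,
) -> AtomPairing:
    """Pair atoms of two models by (guide position, atom name).

    δ is the Euclidean distance in the shared coordinate frame.  No
    superposition is applied by default: both structures live in the fixed
    AGO2 frame, and the statistic is frame-difference sensitive by
    construction.  ``superpose=True`` applies an optimal (Kabsch) rigid
    superposition of the selected modified atoms onto the unmodified ones
    first — an explicitly off-default, exploratory mode.
    """
    orphans: list[str] = []
    matched: list[tuple[Atom, Atom]] = []
    for pos in sorted(selection):
        for name in selection[pos]:
            name = normalize_atom_name(name)
            a = b = None
            try:
                a = modified.residue(pos).atom(name)
            except KeyError:
                orphans.append(f"modified:{pos}/{name}")
            try:
                b = unmodified.residue(pos).atom(name)
            except KeyError:
                orphans.append(f"unmodified:{pos}/{name}")
            if a is not None and b is not None:
                matched.append((a, b))
    if orphans:
        raise PairingError(f"unmatched atoms: {', '.join(orphans)}")
    if not matched:
        raise PairingError("empty selection")

    mod_xyz = np.array([a.coords for a, _ in matched])
    unmod_xyz = np.array([b.coords for _, b in matched])
    if superpose:
        mod_xyz = _kabsch_transform(mod_xyz, unmod_xyz)
    deltas = np.linalg.norm(mod_xyz - unmod_xyz, axis=1)
    return AtomPairing(
        [(a, b, float(d)) for (a, b), d in zip(matched, deltas)])


def heavy_atom_selection(model: StructureModel, positions: Iterable[int]) -> dict[int, tuple[str, ...]]:
    """Selection mapping position -> nucleobase heavy-atom names for ``positions``."""
    selection = {}
    for pos in positions:
        res = model.residue(pos)
        nucleobase_heavy_atoms(res)  # validates completeness
        selection[pos] = NUCLEOBASE_HEAVY_ATOMS[res.base]
    return selection
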