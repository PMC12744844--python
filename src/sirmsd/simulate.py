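"""Synthetic fixtures with known ground truth.

Every input the analysis modules consume can be generated here with its
truth recorded in a :class:`FixtureManifest`: idealized helical guide-RNA
structures with declared bond topology, controlled structural perturbations
with analytically known siRMSD, reporter triplicates with multiplicative
noise around planted activities, two-state melting curves with a planted
midpoint, and expression matrices with a planted SM down-shift and 3'UTRs
carrying planted seed-match sites.

The structural generator is an *idealized* helix (A-form-like rise and
twist, planar rings, standard bond lengths and angles), not a physically
accurate nucleic-acid model: the siRMSD statistic depends only on
displacement fields between two structures, so geometric realism buys
nothing for testing it.  The 2'-substituent geometries double as synthetic
stand-ins for DFT-optimized modified riboses; their conformations follow a
fixed rule — all torsions anti, except gauche for O–C–C–O (the 2'-MOE
gauche effect) and for the acetal C–O–C–O linkages (anomeric effect).

All generators are pure functions of (parameters, seed); there is no global
random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .assays import ReporterMeasurement
from .core import WindowSpec
from .errors import SirmsdError
from .melting import MeltingCurve
from .offtarget import normalize_dna, seed_match_site, seed_of
from .structures import (
    BASES,
    MODIFICATIONS,
    NUCLEOBASE_HEAVY_ATOMS,
    Atom,
    Residue,
    StructureModel,
)

#: 21-nt synthetic guide strand used as the default for expression fixtures.
DEFAULT_GUIDE = "UACGGAUCAAUCGGCCAAUUU"


@dataclass
class FixtureManifest:
    """Declared truth of a generated fixture: parameters and planted values."""

    seed: Optional[int]
    params: dict = field(default_factory=dict)
    truths: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            raise TypeError(f"not JSON serializable: {type(obj)}")
        return json.dumps({"seed": self.seed, "params": self.params,
                           "truths": self.truths}, indent=2, default=_default)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate placement: the new atom D is bonded to ``c`` with
    bond length ``bond``, angle D–c–b and dihedral D–c–b–a."""
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(theta),
                  bond * math.sin(theta) * math.cos(phi),
                  bond * math.sin(theta) * math.sin(phi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _tetra_pair(center: np.ndarray, nb1: np.ndarray, nb2: np.ndarray,
                half_angle_deg: float = 54.25) -> tuple[np.ndarray, np.ndarray]:
    """Two unit directions completing a rough tetrahedron around ``center``
    whose two known neighbors are ``nb1`` and ``nb2``."""
    u1, u2 = _unit(nb1 - center), _unit(nb2 - center)
    bisector = -_unit(u1 + u2)
    axis = _unit(np.cross(u1, u2))
    c, s = math.cos(math.radians(half_angle_deg)), math.sin(math.radians(half_angle_deg))
    return _unit(c * bisector + s * axis), _unit(c * bisector - s * axis)


# ---------------------------------------------------------------------------
# nucleobase templates (planar, idealized)
# ---------------------------------------------------------------------------

_RING_BOND = 1.39      # aromatic ring bond (Å)
_C_O_CARBONYL = 1.23
_C_N_AMINE = 1.35
_C_C_METHYL = 1.50
_C_H_AROMATIC = 1.08
_N_H = 1.01


def _base_template(base: str) -> tuple[dict[str, np.ndarray], list[tuple[str, str]]]:
    """Planar idealized nucleobase in the xy-plane.

    Returns atom positions (glycosidic nitrogen toward -y) and the declared
    bond list.  Ring systems are regular polygons with side 1.39 Å;
    exocyclic atoms sit on the radial through their ring vertex.
    """
    coords: dict[str, np.ndarray] = {}
    bonds: list[tuple[str, str]] = []

    hex_names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    for k, name in enumerate(hex_names):
        ang = math.radians(90.0 + 60.0 * k)
        coords[name] = _RING_BOND * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(6):
        bonds.append((hex_names[i], hex_names[(i + 1) % 6]))

    def radial(vertex: str, name: str, bond: float) -> None:
        coords[name] = coords[vertex] + _unit(coords[vertex]) * bond
        bonds.append((vertex, name))

    purine = base in ("A", "G")
    if purine:
        # pentagon fused on the C4-C5 edge, on the far side of the hexagon
        p4, p5 = coords["C4"], coords["C5"]
        mid = (p4 + p5) / 2.0
        s = float(np.linalg.norm(p5 - p4))
        apothem = s / (2.0 * math.tan(math.radians(36.0)))
        circum = s / (2.0 * math.sin(math.radians(36.0)))
        center = mid + _unit(mid) * apothem
        a4 = math.atan2(*(p4 - center)[[1, 0]])
        a5 = math.atan2(*(p5 - center)[[1, 0]])
        delta = (a5 - a4) % (2.0 * math.pi)
        if delta > math.pi:
            delta -= 2.0 * math.pi
        for j, name in enumerate(("N9", "C8", "N7"), start=1):
            ang = a4 - j * delta
            coords[name] = center + circum * np.array([math.cos(ang), math.sin(ang), 0.0])
        bonds += [("C4", "N9"), ("N9", "C8"), ("C8", "N7"), ("N7", "C5")]

        def radial_p(vertex: str, name: str, bond: float) -> None:
            coords[name] = coords[vertex] + _unit(coords[vertex] - center) * bond
            bonds.append((vertex, name))

        if base == "A":
            radial("C6", "N6", _C_N_AMINE)
            radial("C2", "H2", _C_H_AROMATIC)
        else:  # G
            radial("C6", "O6", _C_O_CARBONYL)
            radial("C2", "N2", _C_N_AMINE)
            radial("N1", "H1", _N_H)
        radial_p("C8", "H8", _C_H_AROMATIC)
        glyco = "N9"
        glyco_dir = _unit(coords["N9"] - center)
    else:
        radial("C2", "O2", _C_O_CARBONYL)
        if base == "C":
            radial("C4", "N4", _C_N_AMINE)
            radial("C5", "H5", _C_H_AROMATIC)
        else:  # U or T
            radial("C4", "O4", _C_O_CARBONYL)
            radial("N3", "H3", _N_H)
            if base == "T":
                radial("C5", "C7", _C_C_METHYL)
            else:
                radial("C5", "H5", _C_H_AROMATIC)
        radial("C6", "H6", _C_H_AROMATIC)
        glyco = "N1"
        glyco_dir = _unit(coords["N1"])

    # orient so the glycosidic direction (ring -> C1') points along -y
    target = np.array([0.0, -1.0, 0.0])
    cosang = float(np.clip(np.dot(glyco_dir[:2], target[:2]), -1, 1))
    ang = math.atan2(glyco_dir[0] * target[1] - glyco_dir[1] * target[0], cosang)
    rot = np.array([[math.cos(ang), -math.sin(ang), 0.0],
                    [math.sin(ang), math.cos(ang), 0.0],
                    [0.0, 0.0, 1.0]])
    shift = coords[glyco].copy()
    for name in coords:
        coords[name] = rot @ (coords[name] - shift)
    return coords, bonds


_GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1", "T": "N1"}

_SUGAR_RING_BOND = 1.45
_C1_N = 1.47


def _substituent_chain(modification: str):
    """Atom recipe for the 2' substituent beyond the first atom.

    Each entry: (name, ref names (a, b, c), bond, angle, torsion).  The
    first substituent atom itself is placed along the exocyclic direction by
    the sugar builder.
    """
    if modification == "RNA":
        return [("HO2'", ("C1'", "C2'", "O2'"), 0.96, 108.5, 180.0)]
    if modification in ("DNA", "FLUORO"):
        return []
    if modification == "OME":
        return [
            ("CM2", ("C1'", "C2'", "O2'"), 1.43, 113.0, 180.0),
            ("HM21", ("C2'", "O2'", "CM2"), 1.09, 109.5, 180.0),
            ("HM22", ("C2'", "O2'", "CM2"), 1.09, 109.5, 60.0),
            ("HM23", ("C2'", "O2'", "CM2"), 1.09, 109.5, -60.0),
        ]
    if modification == "FA":
        # 2'-formamido: C2'-NH-CHO, planar trans amide, carbonyl O anti to C2'
        return [
            ("CF2", ("C1'", "C2'", "N2'"), 1.36, 121.0, 180.0),
            ("HN2", ("C1'", "C2'", "N2'"), 1.01, 118.0, 0.0),
            ("OF2", ("C2'", "N2'", "CF2"), 1.23, 124.0, 180.0),
            ("HF2", ("C2'", "N2'", "CF2"), 1.10, 113.0, 0.0),
        ]
    if modification == "MOE":
        # O2'-CH2-CH2-O-CH3; O-C-C-O gauche (+60), remaining torsions anti
        return [
            ("CA2", ("C1'", "C2'", "O2'"), 1.43, 113.0, 180.0),
            ("CB2", ("C2'", "O2'", "CA2"), 1.51, 109.5, 180.0),
            ("OC2", ("O2'", "CA2", "CB2"), 1.42, 109.5, 60.0),
            ("CD2", ("CA2", "CB2", "OC2"), 1.42, 112.0, 180.0),
            ("HA21", ("C2'", "O2'", "CA2"), 1.09, 109.5, 60.0),
            ("HA22", ("C2'", "O2'", "CA2"), 1.09, 109.5, -60.0),
            ("HB21", ("O2'", "CA2", "CB2"), 1.09, 109.5, 180.0),
            ("HB22", ("O2'", "CA2", "CB2"), 1.09, 109.5, -60.0),
            ("HD21", ("CB2", "OC2", "CD2"), 1.09, 109.5, 180.0),
            ("HD22", ("CB2", "OC2", "CD2"), 1.09, 109.5, 60.0),
            ("HD23", ("CB2", "OC2", "CD2"), 1.09, 109.5, -60.0),
        ]
    if modification == "MTMM":
        # O2'-CH2-O-CH2-S-CH3; acetal C-O-C-O torsions gauche (anomeric),
        # the thioether torsions anti
        return [
            ("CA2", ("C1'", "C2'", "O2'"), 1.40, 114.0, 180.0),
            ("OB2", ("C2'", "O2'", "CA2"), 1.40, 112.0, 60.0),
            ("CB2", ("O2'", "CA2", "OB2"), 1.41, 114.0, 60.0),
            ("SC2", ("CA2", "OB2", "CB2"), 1.81, 109.0, 180.0),
            ("CS2", ("OB2", "CB2", "SC2"), 1.80, 99.0, 180.0),
            ("HA21", ("C2'", "O2'", "CA2"), 1.09, 109.5, -60.0),
            ("HA22", ("C2'", "O2'", "CA2"), 1.09, 109.5, 180.0),
            ("HB21", ("CA2", "OB2", "CB2"), 1.09, 109.5, 60.0),
            ("HB22", ("CA2", "OB2", "CB2"), 1.09, 109.5, -60.0),
            ("HS21", ("CB2", "SC2", "CS2"), 1.09, 109.5, 180.0),
            ("HS22", ("CB2", "SC2", "CS2"), 1.09, 109.5, 60.0),
            ("HS23", ("CB2", "SC2", "CS2"), 1.09, 109.5, -60.0),
        ]
    raise SirmsdError(f"unknown modification {modification!r}")


_SUBSTITUENT_FIRST = {
    "RNA": ("O2'", 1.41), "DNA": ("H2''", 1.09), "FLUORO": ("F2'", 1.39),
    "OME": ("O2'", 1.41), "FA": ("N2'", 1.46), "MOE": ("O2'", 1.41),
    "MTMM": ("O2'", 1.41),
}

def make_nucleotide(base: str, modification: str = "RNA",
                    guide_position: int = 1,
                    include_phosphate: bool = True
                    ) -> tuple[Residue, list[tuple[str, str]]]:
    """Build one idealized nucleotide (base + ribose + 2' substituent).

    Returns the residue and its declared bond topology (name pairs, each
    sorted alphabetically).
    """
    if base not in BASES:
        raise SirmsdError(f"unknown base {base!r}")
    if modification not in MODIFICATIONS:
        raise SirmsdError(f"unknown modification {modification!r}")

    coords, bonds = _base_template(base)
    glyco = _GLYCOSIDIC_N[base]

    # C1' along the glycosidic direction (-y), then the ribose ring in a
    # plane tilted out of the base plane.
    coords["C1'"] = coords[glyco] + np.array([0.0, -_C1_N, 0.0])
    bonds.append((glyco, "C1'"))

    ring_normal = _unit(np.array([0.0, -0.35, 0.94]))   # tilt vs base plane
    # ring center sits on the side away from the base (-y half-space)
    toward_center = _unit(np.cross(np.array([1.0, 0.0, 0.0]), ring_normal))
    circum = _SUGAR_RING_BOND / (2.0 * math.sin(math.radians(36.0)))
    center = coords["C1'"] + toward_center * circum
    e1 = _unit(coords["C1'"] - center)
    e2 = np.cross(ring_normal, e1)
    ring_names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    for j, name in enumerate(ring_names[1:], start=1):
        ang = -2.0 * math.pi * j / 5.0   # sign picks the C2'-endo-ish side
        coords[name] = center + circum * (math.cos(ang) * e1 + math.sin(ang) * e2)
    for i in range(5):
        bonds.append((ring_names[i], ring_names[(i + 1) % 5]))

    def exo_dirs(vertex: str) -> tuple[np.ndarray, np.ndarray]:
        v_out = _unit(coords[vertex] - center)
        phi = math.radians(55.0)
        up = _unit(v_out * math.cos(phi) + ring_normal * math.sin(phi))
        down = _unit(v_out * math.cos(phi) - ring_normal * math.sin(phi))
        return up, down

    def put(vertex: str, name: str, direction: np.ndarray, bond: float) -> None:
        coords[name] = coords[vertex] + direction * bond
        bonds.append((vertex, name))

    up1, down1 = exo_dirs("C1'")
    # base nitrogen already occupies one C1' slot; H1' takes the side away
    # from the base
    h1_dir = up1 if np.dot(up1, coords[glyco] - coords["C1'"]) < \
        np.dot(down1, coords[glyco] - coords["C1'"]) else down1
    put("C1'", "H1'", h1_dir, 1.09)

    up2, down2 = exo_dirs("C2'")
    up3, down3 = exo_dirs("C3'")
    up4, down4 = exo_dirs("C4'")
    # substituent points to the side opposite the base (down), H2' up
    first_name, first_bond = _SUBSTITUENT_FIRST[modification]
    put("C2'", first_name, down2, first_bond)
    put("C2'", "H2'", up2, 1.09)
    # O3' on the face opposite the 2' substituent: keeps the inferred bond
    # graph of long 2' chains disjoint from the 3' hydroxyl
    put("C3'", "O3'", up3, 1.42)
    put("C3'", "H3'", down3, 1.09)
    put("C4'", "C5'", up4, 1.51)
    put("C4'", "H4'", down4, 1.09)
    coords["HO3'"] = coords["O3'"] + _unit(coords["O3'"] - coords["C3'"]) * 0.96
    bonds.append(("O3'", "HO3'"))

    coords["O5'"] = place_atom(coords["C3'"], coords["C4'"], coords["C5'"],
                               1.42, 109.5, 180.0)
    bonds.append(("C5'", "O5'"))
    if include_phosphate:
        coords["P"] = place_atom(coords["C4'"], coords["C5'"], coords["O5'"],
                                 1.60, 119.0, 180.0)
        bonds.append(("O5'", "P"))
        for name, torsion in (("OP1", 60.0), ("OP2", -60.0)):
            coords[name] = place_atom(coords["C5'"], coords["O5'"], coords["P"],
                                      1.49, 109.5, torsion)
            bonds.append(("P", name))
    d5a, d5b = _tetra_pair(coords["C5'"], coords["C4'"], coords["O5'"])
    put("C5'", "H5'", d5a, 1.09)
    put("C5'", "H5''", d5b, 1.09)

    # the DNA case is complete at this point (H2'' was placed as the first
    # substituent atom); every other chemistry grows its chain here
    for name, (ra, rb, rc), bond, angle, torsion in _substituent_chain(modification):
        coords[name] = place_atom(coords[ra], coords[rb], coords[rc],
                                  bond, angle, torsion)
        bonds.append((rc, name))

    atoms = []
    for serial, (name, xyz) in enumerate(coords.items(), start=1):
        element = "H" if name.startswith("H") else name[0]
        atoms.append(Atom(serial, name, element, np.asarray(xyz, dtype=float)))
    residue = Residue(guide_position, base, modification, atoms)
    topology = sorted(set(tuple(sorted(b)) for b in bonds))
    return residue, topology


_BACKBONE_AND_SUGAR = {
    "C1'", "C2'", "C3'", "C4'", "O4'", "C5'", "O5'", "O3'", "P", "OP1", "OP2",
    "H1'", "H2'", "H2''", "H3'", "H4'", "H5'", "H5''", "HO2'", "HO3'",
    "O2'", "F2'", "N2'",
}


def _is_base_atom(res: Residue, name: str) -> bool:
    if name in _BACKBONE_AND_SUGAR:
        return False
    # substituent chain atoms carry a "2" in their name tag (CA2, OB2, ...)
    if name.endswith("2") and name not in ("C2", "O2", "N2", "H2"):
        return False
    if name.startswith(("HM", "HA", "HB", "HD", "HS", "HN", "HF")):
        return False
    if name in ("CM2", "CF2", "OF2", "HF2", "CS2", "SC2"):
        return False
    return True


def make_guide_structure(
    sequence: str,
    modifications: Optional[Mapping[int, str]] = None,
    rise: float = 2.8,
    twist: float = 32.7,
    model_id: str = "synthetic-guide",
    seed: Optional[int] = None,
) -> tuple[StructureModel, FixtureManifest]:
    """Idealized helical guide-strand model with declared topology.

    ``sequence`` is 5'→3'; residue k (1-based guide position) is the
    template nucleotide rotated by (k−1)·twist about z and translated by
    (k−1)·rise along z.  ``modifications`` maps guide positions to
    modification codes (default: all RNA).  Deterministic: the ``seed``
    argument is carried into the manifest but no randomness is used.
    """
    sequence = sequence.strip().upper().replace("T", "U")
    if len(sequence) < 1 or any(b not in "AUGC" for b in sequence):
        raise SirmsdError(f"invalid RNA sequence {sequence!r}")
    modifications = dict(modifications or {})
    residues = []
    topology: dict[int, list[tuple[str, str]]] = {}
    for k, base in enumerate(sequence, start=1):
        modification = modifications.get(k, "RNA")
        res, bonds = make_nucleotide(base, modification, guide_position=k)
        ang = math.radians(twist) * (k - 1)
        rot = np.array([[math.cos(ang), -math.sin(ang), 0.0],
                        [math.sin(ang), math.cos(ang), 0.0],
                        [0.0, 0.0, 1.0]])
        shift = np.array([0.0, 0.0, rise * (k - 1)])
        res = Residue(k, res.base, res.modification,
                      [Atom(a.serial, a.name, a.element, rot @ a.coords + shift)
                       for a in res.atoms])
        residues.append(res)
        topology[k] = bonds
    model = StructureModel(model_id, residues, source="SYNTHETIC")
    manifest = FixtureManifest(
        seed=seed,
        params={"sequence": sequence, "rise_A": rise, "twist_deg": twist,
                "modifications": {str(k): v for k, v in modifications.items()}},
        truths={"topology": {str(k): bonds for k, bonds in topology.items()},
                "atom_counts": {str(r.guide_position): len(r.atoms)
                                for r in residues}},
    )
    return model, manifest


def perturb_structure(
    model: StructureModel,
    window: WindowSpec | Sequence[int],
    displacement_sd: float,
    seed: int = 0,
    uniform_shift: Optional[Sequence[float]] = None,
) -> tuple[StructureModel, FixtureManifest]:
    """Displace the nucleobase atoms of the window positions.

    Default: isotropic Gaussian displacement of each base atom
    (sd ``displacement_sd`` per coordinate).  ``uniform_shift`` instead
    applies one rigid translation to the window's base atoms.  Expected
    siRMSD values per nucleotide and per combination mode are computed from
    the *realized* displacements of the heavy atoms by explicit loops and
    recorded in the manifest.
    """
    positions = list(window.members) if isinstance(window, WindowSpec) else list(window)
    rng = np.random.default_rng(seed)
    new_residues = []
    sq_by_pos: dict[int, list[float]] = {p: [] for p in positions}
    for res in model.residues:
        if res.guide_position not in positions:
            new_residues.append(res)
            continue
        heavy = set(NUCLEOBASE_HEAVY_ATOMS[res.base])
        new_atoms = []
        for atom in res.atoms:
            if _is_base_atom(res, atom.name):
                if uniform_shift is not None:
                    disp = np.asarray(uniform_shift, dtype=float)
                else:
                    disp = rng.normal(0.0, displacement_sd, size=3)
                moved = Atom(atom.serial, atom.name, atom.element,
                             atom.coords + disp, atom.occupancy, atom.alt_loc)
                new_atoms.append(moved)
                if atom.name in heavy:
                    # realized squared displacement, by explicit arithmetic
                    dd = 0.0
                    for u in range(3):
                        dd += (moved.coords[u] - atom.coords[u]) ** 2
                    sq_by_pos[res.guide_position].append(dd)
            else:
                new_atoms.append(atom)
        new_residues.append(Residue(res.guide_position, res.base,
                                    res.modification, new_atoms))

    per_nt = {}
    for p in positions:
        sq = sq_by_pos[p]
        per_nt[p] = math.sqrt(sum(sq) / len(sq)) if sq else 0.0
    all_sq = [d for p in positions for d in sq_by_pos[p]]
    expected = {
        "per_nucleotide": {str(p): per_nt[p] for p in positions},
        "pooled": math.sqrt(sum(all_sq) / len(all_sq)),
        "sum_rmsd": sum(per_nt.values()),
        "sum_msd": sum(sum(sq_by_pos[p]) / len(sq_by_pos[p]) for p in positions),
    }
    perturbed = StructureModel(model.model_id + "-perturbed", new_residues,
                               source="SYNTHETIC")
    manifest = FixtureManifest(
        seed=seed,
        params={"positions": positions, "displacement_sd_A": displacement_sd,
                "uniform_shift": None if uniform_shift is None
                else list(map(float, uniform_shift))},
        truths={"expected_sirmsd": expected},
    )
    return perturbed, manifest


# ---------------------------------------------------------------------------
# reporter, melting, expression
# ---------------------------------------------------------------------------

def simulate_reporter(
    true_activities: Mapping[str, float],
    cv: float = 0.08,
    reps: int = 3,
    seed: int = 0,
    control_id: str = "siCont",
    reporter: str = "SM",
    concentrations: Optional[Mapping[str, float]] = None,
    control_ratio: float = 0.5,
    firefly_level: float = 1.0e4,
) -> tuple[list[ReporterMeasurement], FixtureManifest]:
    """Reporter wells with multiplicative log-normal noise.

    ``true_activities`` maps condition id to the planted relative activity
    in % of control; control wells (activity 100%) are appended under
    ``control_id``.  Each well draws independent log-normal factors
    (sd ``cv`` on the log scale) for firefly and for the Renilla/firefly
    ratio, so the planted activity is recovered by
    :func:`sirmsd.assays.relative_activity` up to noise.
    """
    if cv < 0 or reps < 1:
        raise SirmsdError("cv must be >= 0 and reps >= 1")
    if any(v < 0 for v in true_activities.values()):
        raise SirmsdError("activities must be non-negative (% of control)")
    rng = np.random.default_rng(seed)
    concentrations = dict(concentrations or {})
    rows: list[ReporterMeasurement] = []
    for cond, activity in {**dict(true_activities), control_id: 100.0}.items():
        conc = concentrations.get(cond, 5.0)
        for rep in range(1, reps + 1):
            firefly = firefly_level * math.exp(rng.normal(0.0, cv))
            ratio = control_ratio * activity / 100.0 * math.exp(rng.normal(0.0, cv))
            rows.append(ReporterMeasurement(
                sirna_id=cond, reporter=reporter, concentration=conc,
                renilla=firefly * ratio, firefly=firefly, replicate=rep))
    manifest = FixtureManifest(
        seed=seed,
        params={"cv": cv, "reps": reps, "control_id": control_id,
                "control_ratio": control_ratio},
        truths={"activities_pct": dict(true_activities)},
    )
    return rows, manifest


def reporter_table(rows: Sequence[ReporterMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sirna_id": m.sirna_id, "reporter": m.reporter,
        "concentration_nM": m.concentration, "renilla": m.renilla,
        "firefly": m.firefly, "replicate": m.replicate,
    } for m in rows])


def simulate_melting(
    tm: float,
    width: float = 2.5,
    baseline: float = 0.55,
    amplitude: float = 0.13,
    slope: float = 4.0e-4,
    noise_sd: float = 0.0,
    spacing: float = 0.5,
    t_min: float = 30.0,
    t_max: float = 90.0,
    seed: int = 0,
    ramp: str = "heating",
) -> tuple[MeltingCurve, FixtureManifest]:
    """Two-state melting curve: linear baseline plus a logistic transition.

    A(T) = baseline + slope·(T − t_min) + amplitude · σ((T − tm)/width),
    with optional additive Gaussian noise (AU).  The logistic midpoint is
    the planted Tm; a pure linear baseline has zero curvature, so the
    second-derivative estimator is unbiased at the midpoint for this model.
    """
    if not (t_min < tm < t_max):
        raise SirmsdError("planted Tm must lie inside the temperature range")
    if width <= 0 or spacing <= 0 or amplitude <= 0:
        raise SirmsdError("width, spacing and amplitude must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(t_min, t_max + spacing / 2.0, spacing)
    a = baseline + slope * (t - t_min) + amplitude / (1.0 + np.exp(-(t - tm) / width))
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=t.size)
    if ramp == "cooling":
        t, a = t[::-1], a[::-1]
    curve = MeltingCurve(t, a, ramp=ramp)
    manifest = FixtureManifest(
        seed=seed,
        params={"width_C": width, "baseline_AU": baseline,
                "amplitude_AU": amplitude, "slope_AU_per_C": slope,
                "noise_sd_AU": noise_sd, "spacing_C": spacing},
        truths={"tm_C": tm},
    )
    return curve, manifest


@dataclass
class ExpressionFixture:
    matrix: pd.DataFrame          # transcripts x [mock, treated]
    sm: pd.Series                 # planted SM flags
    utrs: dict[str, str]          # transcript_id -> 3'UTR DNA
    guide: str
    manifest: FixtureManifest

    def utr_fasta(self) -> str:
        chunks = []
        for tid, seq in self.utrs.items():
            chunks.append(f">{tid}")
            chunks.extend(seq[i:i + 70] for i in range(0, len(seq), 70))
        return "\n".join(chunks) + "\n"


def simulate_expression(
    n_transcripts: int = 2000,
    sm_fraction: float = 0.1,
    effect_l2fc: float = -1.0,
    noise_sd: float = 0.25,
    utr_length: int = 300,
    seed: int = 0,
    guide: str = DEFAULT_GUIDE,
    base_log2_mean: float = 9.0,
    base_log2_sd: float = 1.5,
) -> ExpressionFixture:
    """Expression matrix with a planted SM down-shift and matching 3'UTRs.

    SM transcripts carry the guide seed's reverse complement planted at a
    random position of their 3'UTR and an ``effect_l2fc`` shift of the
    treated sample; non-SM UTRs are rejection-sampled to be free of the
    site.  Both samples get independent Gaussian noise (sd ``noise_sd``) on
    the log2 scale.
    """
    if not 0.0 < sm_fraction < 1.0:
        raise SirmsdError("sm_fraction must be in (0, 1)")
    if utr_length < 7:
        raise SirmsdError("utr_length must be >= 7")
    rng = np.random.default_rng(seed)
    seed7 = seed_of(guide)
    site = seed_match_site(seed7)

    n_sm = max(1, int(round(n_transcripts * sm_fraction)))
    ids = [f"NM_{100000 + i}" for i in range(n_transcripts)]
    sm_flags = np.zeros(n_transcripts, dtype=bool)
    sm_flags[rng.choice(n_transcripts, size=n_sm, replace=False)] = True

    alphabet = np.array(list("ACGT"))

    def random_utr() -> str:
        while True:
            s = "".join(rng.choice(alphabet, size=utr_length))
            if site not in s:
                return s

    utrs: dict[str, str] = {}
    for tid, is_sm in zip(ids, sm_flags):
        s = random_utr()
        if is_sm:
            pos = int(rng.integers(0, utr_length - 7 + 1))
            s = s[:pos] + site + s[pos + 7:]
        utrs[tid] = normalize_dna(s)

    base = rng.normal(base_log2_mean, base_log2_sd, size=n_transcripts)
    mock_log = base + rng.normal(0.0, noise_sd, size=n_transcripts)
    treated_log = (base + effect_l2fc * sm_flags
                   + rng.normal(0.0, noise_sd, size=n_transcripts))
    matrix = pd.DataFrame({"mock": 2.0 ** mock_log, "treated": 2.0 ** treated_log},
                          index=pd.Index(ids, name="transcript_id"))
    manifest = FixtureManifest(
        seed=seed,
        params={"n_transcripts": n_transcripts, "sm_fraction": sm_fraction,
                "noise_sd_l2": noise_sd, "utr_length": utr_length,
                "guide": guide},
        truths={"effect_l2fc": effect_l2fc, "seed7": seed7, "site": site,
                "n_sm": int(sm_flags.sum())},
    )
    return ExpressionFixture(matrix=matrix,
                             sm=pd.Series(sm_flags, index=matrix.index),
                             utrs=utrs, guide=guide, manifest=manifest)


def simulate_qc_flags(ids: Sequence[str], fail_fraction: float = 0.3,
                      seed: int = 0) -> tuple[pd.DataFrame, FixtureManifest]:
    """QC-flag table with a planted fraction of failing records."""
    from .offtarget import QC_PASSING_VALUES

    rng = np.random.default_rng(seed)
    n = len(ids)
    table = pd.DataFrame({"SystematicName": list(ids)})
    for flag, passing in QC_PASSING_VALUES.items():
        table[flag] = passing
    n_fail = int(round(n * fail_fraction))
    fail_idx = rng.choice(n, size=n_fail, replace=False)
    flags = list(QC_PASSING_VALUES)
    for i in fail_idx:
        flag = flags[int(rng.integers(0, len(flags)))]
        table.loc[i, flag] = 1 - QC_PASSING_VALUES[flag]
    manifest = FixtureManifest(
        seed=seed, params={"fail_fraction": fail_fraction},
        truths={"n_surviving": int(n - n_fail)})
    return table, manifest
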