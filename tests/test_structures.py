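"""Structure reading, atom selection and pairing."""

import math

import numpy as np
import pytest

from sirmsd.errors import (
    AnnotationError,
    IncompleteResidueError,
    PairingError,
    PdbParseError,
    UnsupportedFeatureError,
)
from sirmsd.simulate import make_guide_structure, make_nucleotide
from sirmsd.structures import (
    NUCLEOBASE_HEAVY_ATOMS,
    Atom,
    Residue,
    StructureModel,
    nucleobase_heavy_atoms,
    normalize_atom_name,
    pair_by_name,
    read_annotated_xyz,
    read_pdb,
    write_pdb,
)

from oracles import brute_force_distances

ATOM_LINE = ("ATOM      1  N1    U A   2      "
             "11.104   6.134  -6.504  1.00  0.00           N")


class TestReadPdb:
    def test_single_record(self):
        model = read_pdb(ATOM_LINE)
        assert len(model.residues) == 1
        res = model.residues[0]
        assert res.guide_position == 2
        assert res.base == "U" and res.modification == "RNA"
        assert res.atoms[0].name == "N1"
        np.testing.assert_allclose(res.atoms[0].coords, [11.104, 6.134, -6.504])

    def test_alt_loc_keeps_highest_occupancy(self):
        line_a = ATOM_LINE[:16] + "A" + ATOM_LINE[17:54] + "  0.60" + ATOM_LINE[60:]
        line_b = ATOM_LINE[:16] + "B" + ATOM_LINE[17:54] + "  0.40" + ATOM_LINE[60:]
        line_b = line_b[:30] + "  12.000" + line_b[38:]
        model = read_pdb(line_a + "\n" + line_b)
        res = model.residues[0]
        assert len(res.atoms) == 1
        assert res.atoms[0].occupancy == 0.60
        assert res.atoms[0].coords[0] == pytest.approx(11.104)

    def test_alt_loc_tie_breaks_to_smallest_code(self):
        line_b = ATOM_LINE[:16] + "B" + ATOM_LINE[17:54] + "  0.50" + ATOM_LINE[60:]
        line_a = ATOM_LINE[:16] + "A" + ATOM_LINE[17:54] + "  0.50" + ATOM_LINE[60:]
        line_a = line_a[:30] + "  12.000" + line_a[38:]
        model = read_pdb(line_b + "\n" + line_a)
        assert model.residues[0].atoms[0].alt_loc == "A"

    def test_malformed_record_names_line(self):
        bad = ATOM_LINE[:30] + "  xx.xxx" + ATOM_LINE[38:]
        with pytest.raises(PdbParseError, match="line 2"):
            read_pdb(ATOM_LINE + "\n" + bad)

    def test_insertion_code_rejected(self):
        bad = ATOM_LINE[:26] + "A" + ATOM_LINE[27:]
        with pytest.raises(UnsupportedFeatureError, match="insertion code"):
            read_pdb(bad)

    def test_fixture_round_trip_counts(self):
        model, manifest = make_guide_structure("GAU")
        back = read_pdb(write_pdb(model))
        for res in back.residues:
            expected = manifest.truths["atom_counts"][str(res.guide_position)]
            assert len(res.atoms) == expected

    def test_hydrogens_retained(self):
        model, _ = make_guide_structure("U")
        back = read_pdb(write_pdb(model))
        assert any(a.is_hydrogen for a in back.residues[0].atoms)


class TestAnnotatedXyz:
    MAP_HEADER = "guide_position\tbase\tmodification\tatom_name\n"

    def test_three_row_fragment(self):
        coords = "N 0 0 0\nC 1.4 0 0\nO 2.1 1.1 0\n"
        amap = self.MAP_HEADER + "3\tU\tRNA\tN1\n3\tU\tRNA\tC2\n3\tU\tRNA\tO2\n"
        model = read_annotated_xyz(coords, amap)
        assert len(model.residues) == 1
        assert len(model.residues[0].atoms) == 3
        assert model.source == "XYZ_ANNOTATED"

    def test_element_disagreement_names_row(self):
        coords = "C 0 0 0\n"
        amap = self.MAP_HEADER + "3\tU\tRNA\tN1\n"
        with pytest.raises(AnnotationError, match="row 1"):
            read_annotated_xyz(coords, amap)

    def test_row_count_mismatch(self):
        with pytest.raises(AnnotationError, match="mismatch"):
            read_annotated_xyz("N 0 0 0\n", self.MAP_HEADER)

    def test_cross_format_round_trip(self):
        model, _ = make_guide_structure("AU")
        rows, mapping = [], [self.MAP_HEADER.rstrip()]
        for res in model.residues:
            for atom in res.atoms:
                x, y, z = atom.coords
                rows.append(f"{atom.element} {x:.6f} {y:.6f} {z:.6f}")
                mapping.append(
                    f"{res.guide_position}\t{res.base}\t{res.modification}\t{atom.name}")
        xyz_model = read_annotated_xyz("\n".join(rows), "\n".join(mapping))
        for res in model.residues:
            other = xyz_model.residue(res.guide_position)
            for atom in res.atoms:
                np.testing.assert_allclose(other.atom(atom.name).coords,
                                           atom.coords, atol=1e-6)


class TestNucleobaseHeavyAtoms:
    @pytest.mark.parametrize("base,count", [("A", 10), ("G", 11), ("C", 8),
                                            ("U", 8), ("T", 9)])
    def test_counts_depend_only_on_base(self, base, count):
        res, _ = make_nucleotide(base, "RNA", 1)
        atoms = nucleobase_heavy_atoms(res)
        assert len(atoms) == count
        assert [a.name for a in atoms] == list(NUCLEOBASE_HEAVY_ATOMS[base])

    def test_adenine_names(self):
        res, _ = make_nucleotide("A", "RNA", 1)
        names = {a.name for a in nucleobase_heavy_atoms(res)}
        assert names == {"N1", "C2", "N3", "C4", "C5", "C6", "N6", "N7", "C8", "N9"}

    def test_uracil_names(self):
        res, _ = make_nucleotide("U", "RNA", 1)
        names = {a.name for a in nucleobase_heavy_atoms(res)}
        assert names == {"N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"}

    def test_no_hydrogens_returned(self):
        res, _ = make_nucleotide("U", "RNA", 1)
        assert all(not a.is_hydrogen for a in nucleobase_heavy_atoms(res))

    def test_missing_atom_listed(self):
        res, _ = make_nucleotide("U", "RNA", 1)
        stripped = Residue(1, "U", "RNA",
                           [a for a in res.atoms if a.name not in ("O4", "C5")])
        with pytest.raises(IncompleteResidueError, match=r"\['O4', 'C5'\]"):
            nucleobase_heavy_atoms(stripped)

    def test_thymine_legacy_methyl_name_accepted(self):
        assert normalize_atom_name(" C5M") == "C7"
        assert normalize_atom_name("C2*") == "C2'"


def _single_atom_model(name, element, coords, pos=1, base="U"):
    res, _ = make_nucleotide(base, "RNA", pos)
    return StructureModel("m", [res])


class TestPairing:
    def _models(self):
        model, _ = make_guide_structure("UAC")
        return model

    def test_identical_models_zero(self):
        model = self._models()
        sel = {2: NUCLEOBASE_HEAVY_ATOMS["A"]}
        pairing = pair_by_name(model, model, sel)
        assert pairing.K == 10
        assert np.all(pairing.deltas == 0.0)

    def test_translation_pythagoras(self):
        model = self._models()
        shifted = model.translated((0.3, 0.0, 0.4))
        sel = {1: NUCLEOBASE_HEAVY_ATOMS["U"]}
        pairing = pair_by_name(shifted, model, sel)
        np.testing.assert_allclose(pairing.deltas, 0.5, atol=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        model = self._models()
        jitter = model.translated((0, 0, 0))
        for res in jitter.residues:
            res.atoms = [Atom(a.serial, a.name, a.element,
                              a.coords + rng.normal(0, 0.5, 3))
                         for a in res.atoms]
        sel = {3: NUCLEOBASE_HEAVY_ATOMS["C"][:5]}
        pairing = pair_by_name(jitter, model, sel)
        a = [tuple(model.residue(3).atom(n).coords) for n in sel[3]]
        b = [tuple(jitter.residue(3).atom(n).coords) for n in sel[3]]
        np.testing.assert_allclose(pairing.deltas,
                                   brute_force_distances(b, a), rtol=1e-12)

    def test_symmetric_in_arguments(self):
        model = self._models()
        shifted = model.translated((1.0, -2.0, 0.5))
        sel = {2: NUCLEOBASE_HEAVY_ATOMS["A"]}
        d1 = pair_by_name(shifted, model, sel).deltas
        d2 = pair_by_name(model, shifted, sel).deltas
        np.testing.assert_allclose(d1, d2)

    def test_rigid_translation_of_both_leaves_deltas(self):
        model = self._models()
        shifted = model.translated((0.2, 0.1, -0.3))
        sel = {1: NUCLEOBASE_HEAVY_ATOMS["U"]}
        before = pair_by_name(shifted, model, sel).deltas
        after = pair_by_name(shifted.translated((5, 5, 5)),
                             model.translated((5, 5, 5)), sel).deltas
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_orphans_reported_on_both_sides(self):
        model = self._models()
        with pytest.raises(PairingError, match="unmatched"):
            pair_by_name(model, model, {2: ("N1", "XX9")})

    def test_superpose_removes_rigid_motion(self):
        model = self._models()
        shifted = model.translated((1.0, 2.0, 3.0))
        sel = {2: NUCLEOBASE_HEAVY_ATOMS["A"]}
        pairing = pair_by_name(shifted, model, sel, superpose=True)
        assert np.max(pairing.deltas) < 1e-8
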