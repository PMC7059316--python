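import numpy as np
import pytest

from cspfrag import (CrystalStructure, Molecule, UnitCell, build_supercell,
                     dihedral_scan_grid, embed_in_vacuum, measure_dihedral,
                     min_image_distance, parse_cif, perceive_molecules,
                     write_cif)
from cspfrag.crystal_io import (AtomSite, CifParseError, cell_dipole,
                                expand_symmetry, shortest_axis)


class TestParseCif:
    def test_minimal_p1(self, minimal_cif_text):
        s = parse_cif(minimal_cif_text)
        assert s.n_sites == 1
        assert s.cell.volume == pytest.approx(125.0)
        assert np.allclose(s.sites[0].frac, [0.1, 0.2, 0.3])

    def test_inversion_doubles_general_position(self, inversion_cif_text):
        s = parse_cif(inversion_cif_text)
        assert s.n_sites == 2
        fracs = sorted(tuple(np.round(site.frac, 6)) for site in s.sites)
        assert fracs == [(0.2, 0.3, 0.4), (0.8, 0.7, 0.6)]

    def test_write_then_parse_round_trip(self, toy_dimer_crystal):
        s2 = parse_cif(write_cif(toy_dimer_crystal))
        assert s2.n_sites == toy_dimer_crystal.n_sites
        got = np.sort(s2.frac_coords(), axis=0)
        want = np.sort(toy_dimer_crystal.frac_coords(), axis=0)
        assert np.allclose(got, want, atol=1e-6)

    def test_missing_cell_is_parse_error(self):
        with pytest.raises(CifParseError):
            parse_cif("data_x\nloop_\n_atom_site_label\n_atom_site_fract_x\nA 0.0\n")

    def test_bad_symmetry_operator_named_in_error(self):
        bad = ("data_x\n_cell_length_a 5\n_cell_length_b 5\n_cell_length_c 5\n"
               "loop_\n_symmetry_equiv_pos_as_xyz\nnonsense$op\n"
               "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
               "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
               "Ar1 Ar 0 0 0\n")
        with pytest.raises(CifParseError, match="nonsense"):
            parse_cif(bad)

    def test_no_symmetry_assumes_p1_with_warning(self, caplog):
        text = ("data_x\n_cell_length_a 5\n_cell_length_b 5\n_cell_length_c 5\n"
                "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
                "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
                "Ar1 Ar 0.1 0.1 0.1\n")
        with caplog.at_level("WARNING", logger="cspfrag"):
            s = parse_cif(text)
        assert s.n_sites == 1
        assert any("P1" in rec.message for rec in caplog.records)

    def test_space_group_number_resolved(self):
        text = ("data_x\n_cell_length_a 6\n_cell_length_b 6\n_cell_length_c 6\n"
                "_space_group_IT_number 2\n"
                "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
                "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
                "Ne1 Ne 0.2 0.3 0.4\n")
        assert parse_cif(text).n_sites == 2

    def test_expansion_idempotent(self, inversion_cif_text):
        s = parse_cif(inversion_cif_text)
        again = expand_symmetry(s.cell, s.sites, s.symmetry_ops)
        assert len(again) == s.n_sites


class TestPerceiveMolecules:
    def test_two_isolated_atoms(self):
        cell = UnitCell(np.eye(3) * 16.0)
        s = CrystalStructure(cell=cell, sites=[
            AtomSite("Ar", [0.1, 0.1, 0.1]), AtomSite("Ar", [0.6, 0.1, 0.1])])
        mols = perceive_molecules(s, radius_scale=1.2)
        assert s.z_molecules == 2
        assert all(m.n_atoms == 1 for m in mols)

    def test_toy_dimer_crystal_z2(self, toy_dimer_crystal):
        mols = perceive_molecules(toy_dimer_crystal)
        assert toy_dimer_crystal.z_molecules == 2
        assert all(m.n_atoms == 2 for m in mols)
        for m in mols:
            assert np.linalg.norm(m.coords[0] - m.coords[1]) == pytest.approx(1.1)

    def test_boundary_bisected_molecule_unwraps(self):
        # bond crosses the cell boundary: atoms at x = 0.95 and x = 0.05+1.1/8-0.05
        cell = UnitCell(np.eye(3) * 8.0)
        s = CrystalStructure(cell=cell, sites=[
            AtomSite("Ar", [0.95, 0.2, 0.2]),
            AtomSite("Ar", [0.95 + 1.1 / 8.0 - 1.0, 0.2, 0.2])])
        (m,) = perceive_molecules(s)
        assert m.n_atoms == 2
        assert np.linalg.norm(m.coords[0] - m.coords[1]) == pytest.approx(1.1)

    def test_translation_invariance_of_perception(self, toy_dimer_crystal):
        shifted = CrystalStructure(
            cell=toy_dimer_crystal.cell,
            sites=[AtomSite(st.element, st.frac + np.array([1.0, 2.0, -1.0]))
                   for st in toy_dimer_crystal.sites])
        a = perceive_molecules(toy_dimer_crystal)
        b = perceive_molecules(shifted)
        assert len(a) == len(b)
        assert sorted(m.formula for m in a) == sorted(m.formula for m in b)

    def test_covalent_network_rejected(self):
        # chain of atoms bonded through the periodic boundary
        cell = UnitCell(np.eye(3) * 1.6)
        s = CrystalStructure(cell=cell, sites=[AtomSite("C", [0.0, 0.0, 0.0])])
        with pytest.raises(ValueError, match="not a molecular crystal"):
            perceive_molecules(s)


class TestSupercell:
    def test_identity_multipliers(self, toy_dimer_crystal):
        perceive_molecules(toy_dimer_crystal)
        sc = build_supercell(toy_dimer_crystal, (1, 1, 1))
        assert sc.n_sites == toy_dimer_crystal.n_sites
        assert sc.cell.volume == pytest.approx(toy_dimer_crystal.cell.volume)

    def test_doubling_shortest_axis_doubles_z(self, toy_dimer_crystal):
        perceive_molecules(toy_dimer_crystal)
        mult = [1, 1, 1]
        mult[shortest_axis(toy_dimer_crystal)] = 2
        sc = build_supercell(toy_dimer_crystal, mult)
        assert sc.z_molecules == 4
        assert len(perceive_molecules(sc)) == 4

    def test_volume_scales_with_determinant(self, toy_dimer_crystal):
        sc = build_supercell(toy_dimer_crystal, (2, 1, 1))
        assert sc.cell.volume == pytest.approx(2 * toy_dimer_crystal.cell.volume)

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1.5, 1, 1), (1, -2, 1), (1, 1)])
    def test_bad_multipliers_rejected(self, toy_dimer_crystal, bad):
        with pytest.raises(ValueError):
            build_supercell(toy_dimer_crystal, bad)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        # cis chain: end atoms on the same side of the central bond
        m = Molecule(["C"] * 4, np.array([
            [-1.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.5, 1.0, 0.0]]))
        assert measure_dihedral(m, [0, 1, 2, 3]) == pytest.approx(0.0, abs=1e-10)

    def test_planar_trans_is_180(self):
        m = Molecule(["C"] * 4, np.array([
            [-1.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.5, -1.0, 0.0]]))
        assert abs(measure_dihedral(m, [0, 1, 2, 3])) == pytest.approx(180.0)

    def test_known_signed_angle_and_mirror_flip(self, butane_like):
        ang = measure_dihedral(butane_like, [0, 1, 2, 3])
        assert abs(ang) == pytest.approx(60.0, abs=1e-8)
        mirrored = Molecule(butane_like.atoms, butane_like.coords * [1, 1, -1])
        assert measure_dihedral(mirrored, [0, 1, 2, 3]) == pytest.approx(-ang)

    def test_collinear_raises(self):
        m = Molecule(["C"] * 4, np.array([
            [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0], [3.0, 1.0, 0.0]]))
        with pytest.raises(ValueError, match="dihedral"):
            measure_dihedral(m, [0, 1, 2, 3])

    def test_scan_grid_has_16_values(self):
        grid = dihedral_scan_grid()
        assert len(grid) == 16
        assert grid[0] == 0.0 and grid[-1] == 150.0
        assert np.allclose(np.diff(grid), 10.0)

    @pytest.mark.parametrize("idx", [[0, 1, 2, 2], [0, 1, 2], [0, 1, 2, 9]])
    def test_bad_indices_rejected(self, butane_like, idx):
        with pytest.raises((ValueError, IndexError)):
            measure_dihedral(butane_like, idx)


class TestEmbedInVacuum:
    @pytest.mark.parametrize("spacing", [15.0, 18.0])
    def test_min_image_spacing_guaranteed(self, simple_molecule, spacing):
        box = embed_in_vacuum(simple_molecule, min_spacing=spacing)
        assert min_image_distance(box) >= spacing - 1e-9

    def test_single_atom_cubic_box(self):
        m = Molecule(["Ar"], np.zeros((1, 3)))
        box = embed_in_vacuum(m, min_spacing=15.0)
        assert np.all(box.cell.lengths >= 15.0 - 1e-12)

    def test_doubled_box_at_least_doubles_spacing(self, simple_molecule):
        box = embed_in_vacuum(simple_molecule, min_spacing=15.0)
        d1 = min_image_distance(box)
        doubled = CrystalStructure(
            cell=UnitCell(box.cell.lattice_matrix * 2.0),
            sites=[AtomSite(s.element, s.frac / 2.0) for s in box.sites])
        assert min_image_distance(doubled) >= 2 * d1 - 1e-9

    def test_empty_fragment_rejected(self):
        with pytest.raises(ValueError):
            embed_in_vacuum([], min_spacing=15.0)


class TestDipoleDetection:
    def test_neutral_default_is_silent(self, simple_molecule):
        d = cell_dipole([simple_molecule])
        assert np.linalg.norm(d) == pytest.approx(0.0)
        assert simple_molecule.net_dipole_flag is False

    def test_polar_cell_flags_and_warns(self, simple_molecule, caplog):
        with caplog.at_level("WARNING", logger="cspfrag"):
            d = cell_dipole([simple_molecule], charges={"O": -0.8, "H": 0.4})
        assert np.linalg.norm(d) > 0
        assert simple_molecule.net_dipole_flag is True
        assert any("dipole" in r.message for r in caplog.records)
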