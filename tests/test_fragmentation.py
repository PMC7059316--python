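import itertools

import numpy as np
import pytest

from cspfrag import (HARTREE_TO_KJMOL, EnergyLedger, ToyPotentialSpec,
                     assemble_hmbi, brute_force_lattice_sum, build_supercell,
                     enumerate_fragments, make_toy_crystal,
                     per_molecule_lattice_energy, perceive_molecules)
from cspfrag.fixtures import ledger_from_potential
from cspfrag.fragmentation import (LedgerError, closest_contact, dimer_key,
                                   export_fragments, molecule_pair_energy)


def brute_force_pair_count(s, cutoff, n_shell=4):
    """Independent per-cell dimer count: ordered pairs over a large image
    block, halved."""
    mols = s.molecules
    lat = s.cell.lattice_matrix
    count = 0
    for i, a in enumerate(mols):
        for j, b in enumerate(mols):
            for t in itertools.product(range(-n_shell, n_shell + 1), repeat=3):
                if i == j and t == (0, 0, 0):
                    continue
                bt = b.translated(np.array(t, dtype=float) @ lat)
                if closest_contact(a, bt) <= cutoff:
                    count += 1
    return count / 2.0


class TestEnumeration:
    def test_simple_cubic_monatomic_neighbor_count(self):
        spec = ToyPotentialSpec(seed=0)
        s, _, _ = make_toy_crystal(spec, molecules_per_cell=1, noise=0.0,
                                   a=4.0, diatomic=False, cutoff=4.1)
        jobs = enumerate_fragments(s, cutoff=4.1)
        # 6 face neighbors of a simple cubic lattice, halved for double counting
        assert jobs.total_dimer_multiplicity() == pytest.approx(3.0)

    def test_cutoff_below_nearest_contact_gives_no_dimers(self):
        spec = ToyPotentialSpec(seed=0)
        s, _, _ = make_toy_crystal(spec, molecules_per_cell=1, noise=0.0,
                                   a=4.0, diatomic=False, cutoff=4.1)
        jobs = enumerate_fragments(s, cutoff=1.0)
        assert jobs.dimers == []

    @pytest.mark.parametrize("z,noise,seed", [(1, 0.0, 1), (2, 0.0, 2),
                                              (2, 0.3, 3), (3, 0.2, 4)])
    def test_multiplicity_conservation(self, z, noise, seed):
        spec = ToyPotentialSpec(seed=seed)
        s, _, jobs = make_toy_crystal(spec, molecules_per_cell=z, noise=noise,
                                      a=7.0, cutoff=8.0)
        assert jobs.total_dimer_multiplicity() == pytest.approx(
            brute_force_pair_count(s, 8.0))

    def test_symmetry_equivalent_molecules_share_monomer_key(self):
        spec = ToyPotentialSpec(seed=5)
        s, _, jobs = make_toy_crystal(spec, molecules_per_cell=2, noise=0.0,
                                      a=7.0, cutoff=8.0)
        # identical rigid diatomics: one unique monomer, multiplicity 2
        assert len(jobs.monomers) == 1
        assert jobs.monomers[0].multiplicity == 2

    def test_enumeration_deterministic(self):
        spec = ToyPotentialSpec(seed=6)
        s, _, _ = make_toy_crystal(spec, molecules_per_cell=2, noise=0.1,
                                   a=7.0, cutoff=8.0)
        a = enumerate_fragments(s, cutoff=8.0)
        b = enumerate_fragments(s, cutoff=8.0)
        assert [d.canonical_key for d in a.dimers] == [d.canonical_key for d in b.dimers]
        assert [d.multiplicity for d in a.dimers] == [d.multiplicity for d in b.dimers]

    def test_bad_cutoff_rejected(self, toy_dimer_crystal):
        perceive_molecules(toy_dimer_crystal)
        with pytest.raises(ValueError):
            enumerate_fragments(toy_dimer_crystal, cutoff=-1.0)

    def test_excessive_shell_bound_rejected(self, toy_dimer_crystal):
        perceive_molecules(toy_dimer_crystal)
        with pytest.raises(ValueError, match="shell"):
            enumerate_fragments(toy_dimer_crystal, cutoff=100.0)


class TestDimerKey:
    def test_ordering_invariance(self, toy_dimer_crystal):
        mols = perceive_molecules(toy_dimer_crystal)
        a, b = mols
        assert dimer_key(a, b) == dimer_key(b, a)

    def test_translation_invariance(self, toy_dimer_crystal):
        a, b = perceive_molecules(toy_dimer_crystal)
        shift = np.array([3.1, -2.2, 0.7])
        assert dimer_key(a, b) == dimer_key(a.translated(shift), b.translated(shift))


class TestAssembly:
    def test_telescoping_identity_high_equals_low(self, toy_crystal_z1):
        _, (s, ledger, jobs) = toy_crystal_z1
        h = assemble_hmbi(jobs, ledger, "LJ", "LJ")
        assert h.total == pytest.approx(ledger.get_periodic("LJ"), abs=1e-12)

    def test_matches_brute_force_lattice_sum(self, toy_crystal_z1):
        spec, (s, ledger, jobs) = toy_crystal_z1
        h = assemble_hmbi(jobs, ledger, "LJ", "LJ")
        e1 = sum(m.multiplicity * ledger.get(m.key, "LJ") for m in jobs.monomers)
        oracle = e1 + brute_force_lattice_sum(s, spec.potential(), 9.0)
        assert h.total == pytest.approx(oracle, abs=1e-8)

    def test_many_body_term_vanishes_for_pairwise_potential(self, toy_crystal_z1):
        _, (s, ledger, jobs) = toy_crystal_z1
        h = assemble_hmbi(jobs, ledger, "LJ", "LJ", sr_cutoff=5.0)
        assert h.lr_split
        assert h.emb_low == pytest.approx(0.0, abs=1e-8)

    def test_total_invariant_to_sr_cutoff_when_levels_match(self, toy_crystal_z1):
        _, (s, ledger, jobs) = toy_crystal_z1
        totals = [assemble_hmbi(jobs, ledger, "LJ", "LJ", sr_cutoff=c).total
                  for c in (3.0, 5.0, 7.0, 9.0)]
        assert np.allclose(totals, totals[0], atol=1e-10)

    def test_perturbing_one_sr_dimer_shifts_total_linearly(self, toy_crystal_z1):
        _, (s, ledger, jobs) = toy_crystal_z1
        # distinct high level that deviates on one dimer only
        delta = 1.5e-3
        target = jobs.dimers[0]
        pert = EnergyLedger(entries=dict(ledger.entries),
                            periodic_low_level=dict(ledger.periodic_low_level))
        for mo in jobs.monomers:
            pert.set(mo.key, "LJ+d", pert.get(mo.key, "LJ"))
        for d in jobs.dimers:
            bump = delta if d.canonical_key == target.canonical_key else 0.0
            pert.set(d.canonical_key, "LJ+d", pert.get(d.canonical_key, "LJ") + bump)
        base = assemble_hmbi(jobs, ledger, "LJ", "LJ").total
        bumped = assemble_hmbi(jobs, pert, "LJ+d", "LJ").total
        assert bumped - base == pytest.approx(delta * target.multiplicity, abs=1e-12)

    def test_dedup_and_no_dedup_assemble_identically(self):
        spec = ToyPotentialSpec(seed=9)
        s, ledger, _ = make_toy_crystal(spec, molecules_per_cell=2, noise=0.2,
                                        a=7.0, cutoff=8.0)
        jobs_dedup = enumerate_fragments(s, cutoff=8.0, deduplicate=True)
        jobs_all = enumerate_fragments(s, cutoff=8.0, deduplicate=False)
        led = ledger_from_potential(s, spec, 8.0, jobs=jobs_dedup)
        led_all = ledger_from_potential(s, spec, 8.0, jobs=jobs_all)
        a = assemble_hmbi(jobs_dedup, led, "LJ", "LJ")
        b = assemble_hmbi(jobs_all, led_all, "LJ", "LJ")
        assert a.total == pytest.approx(b.total, abs=1e-10)
        assert a.e2sr_high == pytest.approx(b.e2sr_high, abs=1e-10)

    def test_missing_ledger_entry_names_fragment(self, toy_crystal_z1):
        _, (s, ledger, jobs) = toy_crystal_z1
        with pytest.raises(LedgerError, match="MP2"):
            assemble_hmbi(jobs, ledger, "MP2", "LJ")

    def test_missing_periodic_energy_rejected(self, toy_crystal_z1):
        _, (s, ledger, jobs) = toy_crystal_z1
        bare = EnergyLedger(entries=dict(ledger.entries))
        with pytest.raises(LedgerError, match="periodic"):
            assemble_hmbi(jobs, bare, "LJ", "LJ")


class TestBruteForceOracle:
    def test_gas_phase_limit_two_molecules(self):
        from cspfrag import CrystalStructure, UnitCell
        from cspfrag.crystal_io import AtomSite

        spec = ToyPotentialSpec(seed=0)
        cell = UnitCell(np.eye(3) * 40.0)
        s = CrystalStructure(cell=cell, sites=[
            AtomSite("Ar", [0.20, 0.20, 0.20]),
            AtomSite("Ar", [0.20 + 5.0 / 40.0, 0.20, 0.20])])
        pot = spec.potential()
        mols = perceive_molecules(s)
        expected = molecule_pair_energy(mols[0], mols[1], pot)
        assert brute_force_lattice_sum(s, pot, 9.0) == pytest.approx(expected, rel=1e-12)

    def test_lj_simple_cubic_lattice_constant(self):
        # LJ lattice sum on simple cubic in reduced units (sigma = a-spacing
        # scaled): compare against an independent double-loop over a block
        spec = ToyPotentialSpec(
            pair_table={("Ar", "Ar"): (1.0e-4, 3.0)}, seed=0)
        s, _, _ = make_toy_crystal(spec, molecules_per_cell=1, noise=0.0,
                                   a=3.5, diatomic=False, cutoff=9.0)
        pot = spec.potential()
        got = brute_force_lattice_sum(s, pot, 3.5 * 2.9)
        # independent summation over explicit integer shifts
        eps, sig = 1.0e-4, 3.0
        ref = 0.0
        for t in itertools.product(range(-4, 5), repeat=3):
            if t == (0, 0, 0):
                continue
            r = 3.5 * np.linalg.norm(t)
            if r <= 3.5 * 2.9:
                sr6 = (sig / r) ** 6
                ref += 4 * eps * (sr6 * sr6 - sr6)
        assert got == pytest.approx(ref / 2.0, rel=1e-12)

    def test_shell_growth_changes_little(self):
        spec = ToyPotentialSpec(seed=0)
        s, _, _ = make_toy_crystal(spec, molecules_per_cell=1, noise=0.0,
                                   a=6.0, cutoff=9.0)
        pot = spec.potential()
        e1 = brute_force_lattice_sum(s, pot, 12.0)
        e2 = brute_force_lattice_sum(s, pot, 24.0, max_shells=8)
        # analytic r^-6 tail bound beyond r_min = 12 - diameter for a
        # density of one diatomic (4 atom pairs) per 6^3 Å^3 cell
        eps, sig = spec.pair_table[("Ar", "Ar")]
        r_min = 12.0 - 1.1
        tail = 4 * (2 * np.pi / 6.0 ** 3) * 4 * eps * sig ** 6 / (3 * r_min ** 3)
        assert abs(e2 - e1) < tail

    def test_overlapping_atoms_rejected(self, toy_dimer_crystal):
        perceive_molecules(toy_dimer_crystal)

        def bad(el_a, el_b, r):
            return float("inf")

        with pytest.raises(ValueError, match="non-finite"):
            brute_force_lattice_sum(toy_dimer_crystal, bad, 6.0)


class TestLatticeEnergy:
    def test_unbound_limit_is_zero(self, toy_crystal_z1):
        _, (s, ledger, jobs) = toy_crystal_z1
        h = assemble_hmbi(jobs, ledger, "LJ", "LJ")
        assert per_molecule_lattice_energy(h, h.per_molecule) == pytest.approx(0.0)

    def test_bound_toy_crystal_negative_and_matches_oracle(self):
        spec = ToyPotentialSpec(seed=21)
        # spacing near the LJ minimum so the crystal binds
        s, ledger, jobs = make_toy_crystal(spec, molecules_per_cell=1, noise=0.0,
                                           a=4.0, diatomic=False, cutoff=9.0)
        h = assemble_hmbi(jobs, ledger, "LJ", "LJ")
        gas = ledger.get(jobs.monomers[0].key, "LJ")
        e_latt = per_molecule_lattice_energy(h, gas)
        oracle = brute_force_lattice_sum(s, spec.potential(), 9.0)
        assert e_latt < 0
        assert e_latt == pytest.approx(oracle * HARTREE_TO_KJMOL, abs=1e-8)

    def test_identical_ledgers_identical_energies(self, toy_crystal_z1):
        _, (s, ledger, jobs) = toy_crystal_z1
        h1 = assemble_hmbi(jobs, ledger, "LJ", "LJ")
        h2 = assemble_hmbi(jobs, ledger, "LJ", "LJ")
        assert per_molecule_lattice_energy(h1, 0.0) == per_molecule_lattice_energy(h2, 0.0)


class TestSupercellConsistency:
    def test_per_molecule_energy_agrees_between_cells(self):
        spec = ToyPotentialSpec(seed=13)
        s, ledger, jobs = make_toy_crystal(spec, molecules_per_cell=1, noise=0.0,
                                           a=6.0, cutoff=9.0)
        h1 = assemble_hmbi(jobs, ledger, "LJ", "LJ")
        sc = build_supercell(s, (2, 2, 2))
        sc.molecules = None
        jobs2 = enumerate_fragments(sc, cutoff=9.0)
        ledger2 = ledger_from_potential(sc, spec, 9.0, jobs=jobs2)
        h2 = assemble_hmbi(jobs2, ledger2, "LJ", "LJ")
        # identical per-molecule totals within the r^-6 truncation tail
        assert h2.per_molecule == pytest.approx(h1.per_molecule, abs=1e-7)


class TestLedgerRoundTrip:
    def test_yaml_round_trip_preserves_assembly(self, toy_crystal_z1):
        _, (s, ledger, jobs) = toy_crystal_z1
        led2 = EnergyLedger.from_yaml(ledger.to_yaml())
        a = assemble_hmbi(jobs, ledger, "LJ", "LJ")
        b = assemble_hmbi(jobs, led2, "LJ", "LJ")
        assert a.total == pytest.approx(b.total, abs=1e-12)

    def test_export_manifest_covers_all_fragments(self, toy_crystal_z1):
        _, (s, ledger, jobs) = toy_crystal_z1
        files = export_fragments(jobs, s)
        assert "manifest.yaml" in files
        n_xyz = sum(1 for name in files if name.endswith(".xyz"))
        assert n_xyz == len(jobs.monomers) + len({d.canonical_key for d in jobs.dimers})
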