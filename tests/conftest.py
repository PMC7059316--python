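import numpy as np
import pytest
import yaml

from cspfrag import (CrystalStructure, Molecule, ToyPotentialSpec, UnitCell,
                     make_polymorph_pair, make_toy_crystal)
from cspfrag.crystal_io import (TAG_FIXED_CELL_RT, TAG_RELAXED_0K, AtomSite,
                                write_cif)
from cspfrag.fixtures import make_frequency_set


def write_pair_workspace(tmp_path, penalty=5.0, gain=6.0, seed=37):
    """Materialize an engineered polymorph pair as a full on-disk workspace
    (CIFs, frequency YAMLs, per-polymorph ledgers, ranking config)."""
    pair = make_polymorph_pair(ToyPotentialSpec(seed=seed),
                               conformational_penalty=penalty,
                               packing_gain=gain)
    cfg = {"reference": "A", "levels": {"high": "LJ", "low": "LJ"},
           "cutoff": 9.0, "temperatures": [423.0], "output": "out",
           "polymorphs": []}
    for name, (s, ledger, jobs) in pair.items():
        structures, frequencies = {}, {}
        for tag in (TAG_RELAXED_0K, TAG_FIXED_CELL_RT):
            cif = tmp_path / f"{name}_{tag}.cif"
            cif.write_text(write_cif(s, name=f"{name}_{tag}"))
            structures[tag] = cif.name
            fq = tmp_path / f"{name}_{tag}.freqs.yaml"
            f = make_frequency_set(24, lo=40.0, hi=400.0, seed=1, z_molecules=2,
                                   structure_tag=tag)
            fq.write_text(f.to_yaml())
            frequencies[tag] = fq.name
        led = tmp_path / f"{name}.ledger.yaml"
        led.write_text(ledger.to_yaml())
        cfg["polymorphs"].append({"name": name, "structures": structures,
                                  "frequencies": frequencies,
                                  "ledger": led.name})
    cfg_path = tmp_path / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg))
    return cfg_path


@pytest.fixture
def pair_workspace_factory(tmp_path):
    def factory(**kwargs):
        return write_pair_workspace(tmp_path, **kwargs)
    return factory


MINIMAL_P1_CIF = """data_minimal
_cell_length_a 5.0
_cell_length_b 5.0
_cell_length_c 5.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_symmetry_equiv_pos_as_xyz
x,y,z
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
Ar1 Ar 0.1 0.2 0.3
"""

INVERSION_CIF = """data_inv
_cell_length_a 6.0
_cell_length_b 6.0
_cell_length_c 6.0
loop_
_symmetry_equiv_pos_as_xyz
x,y,z
-x,-y,-z
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
Ne1 Ne 0.2 0.3 0.4
"""


@pytest.fixture
def minimal_cif_text():
    return MINIMAL_P1_CIF


@pytest.fixture
def inversion_cif_text():
    return INVERSION_CIF


@pytest.fixture
def toy_dimer_crystal():
    """Two Ar2 diatomics per cubic cell: bond 1.1 Å, intermolecular ~3.5+ Å."""
    cell = UnitCell(np.eye(3) * 8.0)
    sites = [
        AtomSite("Ar", [0.10, 0.10, 0.10], "Ar1"),
        AtomSite("Ar", [0.10 + 1.1 / 8.0, 0.10, 0.10], "Ar2"),
        AtomSite("Ar", [0.10, 0.10 + 3.5 / 8.0 + 1.1 / 8.0, 0.10], "Ar3"),
        AtomSite("Ar", [0.10 + 1.1 / 8.0, 0.10 + 3.5 / 8.0 + 1.1 / 8.0, 0.10], "Ar4"),
    ]
    return CrystalStructure(cell=cell, sites=sites)


@pytest.fixture
def simple_molecule():
    """A bent triatomic for dihedral-free geometry checks."""
    return Molecule(["O", "H", "H"],
                    np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0],
                              [-0.24, 0.93, 0.0]]))


@pytest.fixture
def butane_like():
    """Four-atom chain with a +60° dihedral."""
    coords = np.array([
        [1.0, 0.0, 1.0],
        [0.0, 0.0, 0.0],
        [0.0, 0.0, -1.5],
        [np.cos(np.radians(60.0)), np.sin(np.radians(60.0)), -2.5],
    ])
    return Molecule(["C", "C", "C", "C"], coords)


@pytest.fixture(scope="session")
def toy_crystal_z1():
    spec = ToyPotentialSpec(seed=11)
    return spec, make_toy_crystal(spec, molecules_per_cell=1, noise=0.0,
                                  a=6.0, cutoff=9.0)
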