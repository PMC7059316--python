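"""Crystal structures and molecular geometries.

Reads CIF files with symmetry expansion, perceives molecules from periodic
coordinates via a covalent-radius bond criterion, builds supercells, measures
dihedral angles, and embeds fragments in vacuum boxes for gas-phase
calculations.

Units: lengths in Å, angles in degrees.  Energies elsewhere in the package are
stored in Hartree and reported in kJ mol⁻¹ (1 Eh = 2625.4996 kJ mol⁻¹).
Fractional coordinates are wrapped to the half-open interval [0, 1); atom
indexing is 0-based throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import networkx as nx
import numpy as np

logger = logging.getLogger("cspfrag")

#: conversion factor, Hartree -> kJ mol-1
HARTREE_TO_KJMOL = 2625.4996

#: default scaling of summed covalent radii in the bond criterion
DEFAULT_RADIUS_SCALE = 1.2

#: tolerance (fractional) for merging symmetry-duplicated sites
SITE_MERGE_TOL = 1e-3

#: structure-condition tags: fully relaxed (0 K proxy) vs fixed experimental
#: room-temperature cell with relaxed atomic positions
TAG_RELAXED_0K = "relaxed-0K"
TAG_FIXED_CELL_RT = "fixed-cell-RT"


class CifParseError(ValueError):
    """Raised when a CIF document cannot be interpreted."""


def covalent_radius(element: str) -> float:
    """Tabulated covalent radius in Å for a chemical symbol."""
    el = gemmi.Element(element)
    if el.name == "X" or el.covalent_r <= 0:
        raise ValueError(f"no covalent radius tabulated for element {element!r}")
    return float(el.covalent_r)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Crystal lattice; rows of ``lattice_matrix`` are the vectors a, b, c (Å)."""

    lattice_matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.lattice_matrix, dtype=float).reshape(3, 3)
        object.__setattr__(self, "lattice_matrix", m)
        if np.any(np.linalg.norm(m, axis=1) <= 0):
            raise ValueError("lattice vectors must have positive length")
        if np.linalg.det(m) <= 0:
            raise ValueError("cell volume must be positive (right-handed lattice)")

    @classmethod
    def from_parameters(cls, a: float, b: float, c: float,
                        alpha: float = 90.0, beta: float = 90.0,
                        gamma: float = 90.0) -> "UnitCell":
        cell = gemmi.UnitCell(a, b, c, alpha, beta, gamma)
        # gemmi orthogonalization matrix has lattice vectors as columns
        return cls(np.array(cell.orth.mat.tolist()).T)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.lattice_matrix))

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.lattice_matrix, axis=1)

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.lattice_matrix

    def perpendicular_heights(self) -> np.ndarray:
        """Distance between opposite cell faces along each lattice direction."""
        m = self.lattice_matrix
        vol = abs(np.linalg.det(m))
        areas = np.array([
            np.linalg.norm(np.cross(m[(k + 1) % 3], m[(k + 2) % 3]))
            for k in range(3)
        ])
        return vol / areas

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        a, b, c = self.lengths
        m = self.lattice_matrix

        def ang(u, v):
            return math.degrees(math.acos(
                np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))

        return (float(a), float(b), float(c),
                ang(m[1], m[2]), ang(m[0], m[2]), ang(m[0], m[1]))


@dataclass(frozen=True)
class AtomSite:
    """One crystallographic site, fractional coordinates wrapped to [0, 1)."""

    element: str
    frac: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frac, dtype=float) % 1.0
        f[f >= 1.0] -= 1.0  # guard against 0.9999999... % 1.0 == 1.0 after fp
        object.__setattr__(self, "frac", f)
        covalent_radius(self.element)  # validates the symbol


@dataclass
class Molecule:
    """A connected molecular unit, unwrapped to contiguous Cartesian coordinates."""

    atoms: list[str]
    coords: np.ndarray
    cell_index: int = 0
    net_dipole_flag: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.atoms) == 0:
            raise ValueError("molecule must contain at least one atom")
        if len(self.atoms) != len(self.coords):
            raise ValueError("atoms/coords length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def formula(self) -> str:
        counts: dict[str, int] = {}
        for el in self.atoms:
            counts[el] = counts.get(el, 0) + 1
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in sorted(counts.items()))

    def translated(self, shift: np.ndarray) -> "Molecule":
        return Molecule(list(self.atoms), self.coords + np.asarray(shift, dtype=float),
                        cell_index=self.cell_index,
                        net_dipole_flag=self.net_dipole_flag)

    def point_charge_dipole(self, charges: dict[str, float] | None = None) -> np.ndarray:
        """Crude point-charge dipole estimate (e·Å); zero charges by default."""
        if not charges:
            return np.zeros(3)
        q = np.array([charges.get(el, 0.0) for el in self.atoms])
        return q @ self.coords


@dataclass
class CrystalStructure:
    """Unit cell + expanded sites + symmetry operations + perceived molecules."""

    cell: UnitCell
    sites: list[AtomSite]
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    z_molecules: int | None = None
    tag: str = TAG_RELAXED_0K
    molecules: list[Molecule] | None = None

    def __post_init__(self) -> None:
        if not self.symmetry_ops:
            self.symmetry_ops = [(np.eye(3), np.zeros(3))]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def frac_coords(self) -> np.ndarray:
        return np.array([s.frac for s in self.sites]).reshape(-1, 3)

    def cart_coords(self) -> np.ndarray:
        return self.cell.to_cartesian(self.frac_coords())

    def elements(self) -> list[str]:
        return [s.element for s in self.sites]


# ---------------------------------------------------------------------------
# CIF parsing / writing
# ---------------------------------------------------------------------------

_SYMOP_TAGS = ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz")
_SG_NAME_TAGS = ("_space_group_name_H-M_alt", "_symmetry_space_group_name_H-M")
_SG_NUMBER_TAGS = ("_space_group_IT_number", "_symmetry_Int_Tables_number")


def _op_to_matrices(op: gemmi.Op) -> tuple[np.ndarray, np.ndarray]:
    den = float(gemmi.Op.DEN)
    return np.array(op.rot, dtype=float) / den, np.array(op.tran, dtype=float) / den


def _cif_number(raw: str, tag: str) -> float:
    """Parse a CIF numeric value, stripping an su in parentheses."""
    s = raw.split("(")[0]
    try:
        return float(s)
    except ValueError as exc:
        raise CifParseError(f"cannot parse {tag} value {raw!r}") from exc


def _extract_symmetry_ops(block: gemmi.cif.Block) -> list[tuple[np.ndarray, np.ndarray]]:
    for tag in _SYMOP_TAGS:
        triplets = [gemmi.cif.as_string(v) for v in block.find_loop(tag)]
        if not triplets:
            v = block.find_value(tag)
            if v is not None:
                triplets = [gemmi.cif.as_string(v)]
        if triplets:
            ops = []
            for trip in triplets:
                try:
                    ops.append(_op_to_matrices(gemmi.Op(trip)))
                except Exception as exc:
                    raise CifParseError(f"unparseable symmetry operator {trip!r}") from exc
            return ops
    for tag in _SG_NAME_TAGS + _SG_NUMBER_TAGS:
        v = block.find_value(tag)
        if v is None:
            continue
        v = gemmi.cif.as_string(v)
        sg = (gemmi.find_spacegroup_by_number(int(v))
              if tag in _SG_NUMBER_TAGS else gemmi.find_spacegroup_by_name(v))
        if sg is not None:
            return [_op_to_matrices(op) for op in sg.operations()]
        raise CifParseError(f"unknown space group {v!r}")
    logger.warning("CIF has no symmetry information; assuming P1")
    return [(np.eye(3), np.zeros(3))]


def expand_symmetry(cell: UnitCell, sites: Sequence[AtomSite],
                    ops: Sequence[tuple[np.ndarray, np.ndarray]],
                    tol: float = SITE_MERGE_TOL) -> list[AtomSite]:
    """Apply every operation to every site, wrap, and deduplicate at ``tol``.

    Expansion is idempotent: sites already present (within the minimum-image
    fractional tolerance) are not duplicated.
    """
    out: list[AtomSite] = []
    kept: list[np.ndarray] = []
    for site in sites:
        for rot, tran in ops:
            f = (rot @ site.frac + tran) % 1.0
            dup = False
            for other in kept:
                d = f - other
                d -= np.round(d)
                if np.all(np.abs(d) < tol):
                    dup = True
                    break
            if not dup:
                out.append(AtomSite(site.element, f, site.label))
                kept.append(out[-1].frac)
    if len(out) < len(sites) * len(ops):
        n_merged = len(sites) * len(ops) - len(out)
        logger.debug("symmetry expansion merged %d duplicate images", n_merged)
    return out


def parse_cif(text: str, tag: str = TAG_RELAXED_0K) -> CrystalStructure:
    """Parse a CIF document into a symmetry-expanded :class:`CrystalStructure`.

    Accepts ``_symmetry_equiv_pos_as_xyz`` or ``_space_group_symop_operation_xyz``
    loops; falls back to a space-group name/number, then to P1 with a warning.
    """
    try:
        doc = gemmi.cif.read_string(text)
        block = doc.sole_block()
    except Exception as exc:
        raise CifParseError(f"invalid CIF document: {exc}") from exc

    params = {}
    for name in ("a", "b", "c"):
        v = block.find_value(f"_cell_length_{name}")
        if v is None:
            raise CifParseError(f"missing _cell_length_{name}")
        params[name] = _cif_number(gemmi.cif.as_string(v), f"_cell_length_{name}")
    for name in ("alpha", "beta", "gamma"):
        v = block.find_value(f"_cell_angle_{name}")
        params[name] = 90.0 if v is None else _cif_number(
            gemmi.cif.as_string(v), f"_cell_angle_{name}")
    cell = UnitCell.from_parameters(params["a"], params["b"], params["c"],
                                    params["alpha"], params["beta"], params["gamma"])

    table = block.find("_atom_site_", ["label", "fract_x", "fract_y", "fract_z"])
    symbols = list(block.find_loop("_atom_site_type_symbol"))
    if len(table) == 0:
        raise CifParseError("no atom sites found")
    sites = []
    for i, row in enumerate(table):
        label = gemmi.cif.as_string(row[0])
        elem = (gemmi.cif.as_string(symbols[i]) if i < len(symbols)
                else "".join(ch for ch in label if ch.isalpha()))
        elem = elem.strip("+-0123456789")
        frac = [_cif_number(gemmi.cif.as_string(row[k]), "_atom_site_fract") for k in (1, 2, 3)]
        sites.append(AtomSite(elem, np.array(frac), label))

    ops = _extract_symmetry_ops(block)
    expanded = expand_symmetry(cell, sites, ops)
    return CrystalStructure(cell=cell, sites=expanded, symmetry_ops=ops, tag=tag)


def write_cif(s: CrystalStructure, name: str = "cspfrag") -> str:
    """Serialize a structure as a P1 CIF (all sites explicit)."""
    a, b, c, al, be, ga = s.cell.parameters()
    lines = [
        f"data_{name}",
        f"_cell_length_a {a:.8f}",
        f"_cell_length_b {b:.8f}",
        f"_cell_length_c {c:.8f}",
        f"_cell_angle_alpha {al:.6f}",
        f"_cell_angle_beta {be:.6f}",
        f"_cell_angle_gamma {ga:.6f}",
        "_symmetry_space_group_name_H-M 'P 1'",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
        "x,y,z",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for i, site in enumerate(s.sites):
        label = site.label or f"{site.element}{i + 1}"
        x, y, z = site.frac
        lines.append(f"{label} {site.element} {x:.8f} {y:.8f} {z:.8f}")
    return "\n".join(lines) + "\n"


def write_xyz(atoms: Sequence[str], coords: np.ndarray, comment: str = "") -> str:
    """Plain XYZ text block (Å)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    lines = [str(len(atoms)), comment.replace("\n", " ")]
    for el, (x, y, z) in zip(atoms, coords):
        lines.append(f"{el} {x: .10f} {y: .10f} {z: .10f}")
    return "\n".join(lines) + "\n"


def read_xyz(text: str) -> list[Molecule]:
    """Read concatenated XYZ blocks; each block becomes one Molecule."""
    lines = text.splitlines()
    mols = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        body = lines[i + 2:i + 2 + n]
        atoms, coords = [], []
        for ln in body:
            parts = ln.split()
            atoms.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        mols.append(Molecule(atoms, np.array(coords), cell_index=len(mols)))
        i += 2 + n
    if not mols:
        raise ValueError("no XYZ blocks found")
    return mols


# ---------------------------------------------------------------------------
# molecule perception
# ---------------------------------------------------------------------------

def perceive_molecules(s: CrystalStructure,
                       radius_scale: float = DEFAULT_RADIUS_SCALE) -> list[Molecule]:
    """Identify molecules as connected components of the covalent bond graph.

    Atoms i, j are bonded iff their minimum-image distance is at most
    ``radius_scale`` times the sum of their covalent radii.  Components are
    unwrapped across periodic boundaries into contiguous Cartesian geometries.
    A component that bonds to its own periodic image (a covalent network) makes
    the structure non-molecular and raises ``ValueError``.

    Sets ``s.z_molecules`` and ``s.molecules`` as a side effect.
    """
    if radius_scale <= 0:
        raise ValueError("radius_scale must be positive")
    frac = s.frac_coords()
    n = len(frac)
    radii = np.array([covalent_radius(el) for el in s.elements()])
    lat = s.cell.lattice_matrix

    shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                       for k in (-1, 0, 1)], dtype=float)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    # bond list with the image shift that realises each bond
    bond_shift: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n):
        for j in range(i, n):
            d = frac[j] - frac[i] + shifts  # all candidate images of j
            cart = d @ lat
            dist = np.linalg.norm(cart, axis=1)
            if i == j:
                dist[np.all(shifts == 0, axis=1)] = np.inf
            k = int(np.argmin(dist))
            cut = radius_scale * (radii[i] + radii[j])
            if dist[k] <= cut:
                if i == j:
                    raise ValueError(
                        "not a molecular crystal: atom bonds to its own periodic image")
                g.add_edge(i, j)
                bond_shift[(i, j)] = shifts[k]
                # also check for bonding through more than one image of j,
                # which signals a periodic (polymeric) network
                if np.sum(dist <= cut) > 1:
                    raise ValueError(
                        "not a molecular crystal: bonded through multiple periodic images")

    molecules = []
    for ci, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        comp = set(comp)
        seed = min(comp)
        # BFS unwrap: accumulate integer lattice shifts along bonds
        offset = {seed: np.zeros(3)}
        queue = [seed]
        while queue:
            u = queue.pop(0)
            for v in g.neighbors(u):
                sh = bond_shift[(u, v)] if (u, v) in bond_shift else -bond_shift[(v, u)]
                cand = offset[u] + sh
                if v in offset:
                    if not np.allclose(cand, offset[v]):
                        raise ValueError(
                            "not a molecular crystal: inconsistent unwrap "
                            "(component spans periodic images)")
                else:
                    offset[v] = cand
                    queue.append(v)
        idx = sorted(comp)
        coords = np.array([(frac[i] + offset[i]) @ lat for i in idx])
        molecules.append(Molecule([s.sites[i].element for i in idx], coords,
                                  cell_index=ci))

    s.molecules = molecules
    s.z_molecules = len(molecules)
    formulas = {m.formula for m in molecules}
    if len(formulas) > 1:
        logger.info("cell contains %d distinct molecular formulas: %s",
                    len(formulas), sorted(formulas))
    return molecules


def cell_dipole(molecules: Iterable[Molecule],
                charges: dict[str, float] | None = None,
                warn_threshold: float = 1e-6) -> np.ndarray:
    """Net cell dipole from per-molecule point-charge estimates (e·Å).

    A nonzero net dipole is a known failure mode for fragment-based crystal
    energies (conditionally convergent electrostatics); it is detected and
    warned about, not corrected.
    """
    total = np.zeros(3)
    for m in molecules:
        d = m.point_charge_dipole(charges)
        if np.linalg.norm(d) > warn_threshold:
            m.net_dipole_flag = True
        total += d
    if np.linalg.norm(total) > warn_threshold:
        logger.warning(
            "unit cell carries a net dipole (|D| = %.4f e·Å); fragment-based "
            "lattice sums may be ill-conditioned for polar cells", np.linalg.norm(total))
    return total


# ---------------------------------------------------------------------------
# supercells
# ---------------------------------------------------------------------------

def build_supercell(s: CrystalStructure, multipliers: Sequence[int]) -> CrystalStructure:
    """Replicate the cell along each lattice direction.

    Used to equalize the number of molecules per cell (Z) across polymorphs
    before comparing per-cell vibrational thermodynamics, e.g. doubling along
    the shortest axis to bring Z = 2 cells to Z = 4.
    """
    mult = list(multipliers)
    if len(mult) != 3 or any((not float(m).is_integer()) or int(m) < 1 for m in mult):
        raise ValueError("multipliers must be three integers >= 1")
    mult = [int(m) for m in mult]
    new_lat = s.cell.lattice_matrix * np.array(mult, dtype=float)[:, None]
    new_sites = []
    for ta in range(mult[0]):
        for tb in range(mult[1]):
            for tc in range(mult[2]):
                t = np.array([ta, tb, tc], dtype=float)
                for site in s.sites:
                    f = (site.frac + t) / np.array(mult, dtype=float)
                    new_sites.append(AtomSite(site.element, f, site.label))
    z = None if s.z_molecules is None else s.z_molecules * mult[0] * mult[1] * mult[2]
    return CrystalStructure(cell=UnitCell(new_lat), sites=new_sites,
                            symmetry_ops=[(np.eye(3), np.zeros(3))],
                            z_molecules=z, tag=s.tag)


def shortest_axis(s: CrystalStructure) -> int:
    """Index (0, 1, 2) of the shortest lattice vector."""
    return int(np.argmin(s.cell.lengths))


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def measure_dihedral(m: Molecule, atom_indices: Sequence[int]) -> float:
    """Signed dihedral angle (degrees, IUPAC convention) over four atoms.

    Range (−180, 180]; the sign flips under mirror reflection of the
    coordinates.  Raises on out-of-range/duplicate indices or a collinear
    triple (undefined dihedral).
    """
    idx = list(atom_indices)
    if len(idx) != 4 or len(set(idx)) != 4:
        raise ValueError("need four distinct atom indices")
    if any(i < 0 or i >= m.n_atoms for i in idx):
        raise IndexError("atom index out of range")
    p = m.coords[idx]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("undefined dihedral: three consecutive atoms are collinear")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def dihedral_scan_grid(start: float = 0.0, stop: float = 150.0,
                       step: float = 10.0) -> np.ndarray:
    """Grid of fixed dihedral values for a conformational scan.

    The default grid is the 16 values 0–150° in 10° intervals used for the
    torsional profile of the ROY molecule's S–C–N–C angle.
    """
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


# ---------------------------------------------------------------------------
# vacuum embedding
# ---------------------------------------------------------------------------

def embed_in_vacuum(fragment: Molecule | Sequence[Molecule],
                    min_spacing: float = 15.0) -> CrystalStructure:
    """Place a fragment in the smallest axis-aligned P1 box guaranteeing that
    every fragment atom is at least ``min_spacing`` Å from every periodic-image
    atom.  Used to run gas-phase monomer/dimer jobs with periodic codes; 15 Å
    spacing changes gas-phase energies by ≲0.15 kJ mol⁻¹ versus 18 Å.
    """
    if min_spacing <= 0:
        raise ValueError("min_spacing must be positive")
    mols = [fragment] if isinstance(fragment, Molecule) else list(fragment)
    if not mols:
        raise ValueError("empty fragment")
    atoms = [el for m in mols for el in m.atoms]
    coords = np.vstack([m.coords for m in mols])
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    edges = (hi - lo) + min_spacing
    centered = coords - lo + min_spacing / 2.0
    cell = UnitCell(np.diag(edges))
    sites = [AtomSite(el, c / edges, f"{el}{i+1}")
             for i, (el, c) in enumerate(zip(atoms, centered))]
    return CrystalStructure(cell=cell, sites=sites, z_molecules=len(mols))


def min_image_distance(s: CrystalStructure) -> float:
    """Smallest distance between any atom and any atom in a neighboring image."""
    cart = s.cart_coords()
    lat = s.cell.lattice_matrix
    best = math.inf
    for ia in (-1, 0, 1):
        for ib in (-1, 0, 1):
            for ic in (-1, 0, 1):
                if ia == ib == ic == 0:
                    continue
                shift = np.array([ia, ib, ic], dtype=float) @ lat
                d = np.linalg.norm(cart[:, None, :] - (cart[None, :, :] + shift), axis=-1)
                best = min(best, float(d.min()))
    return best
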