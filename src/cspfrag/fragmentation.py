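"""Many-body-expansion bookkeeping and the hybrid fragment lattice energy.

The crystal energy per unit cell is partitioned as

    U_el = E1(high) + E2_SR(high) + E2_LR(low) + E_many-body(low)

where the intramolecular (1-body) terms and short-range pairwise (2-body)
interactions are taken at an accurate correlated level, while the long-range
2-body and collective many-body terms come from a cheap periodic mean-field
level.  This module enumerates the symmetry/translation-unique monomers and
periodic dimers with multiplicities, stores per-fragment energies in a ledger
keyed by geometry-derived canonical identifiers, and assembles the hybrid
total.  A brute-force pairwise lattice sum serves as the independent oracle
for the bookkeeping.

Energies are stored in Hartree throughout; reported deltas are in kJ mol⁻¹.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import yaml

from .crystal_io import HARTREE_TO_KJMOL, CrystalStructure, Molecule, perceive_molecules

#: default short-range 2-body cutoff (Å, closest interatomic contact)
DEFAULT_SR_CUTOFF = 9.0

#: distance quantization (Å) used when hashing geometries into canonical keys
KEY_QUANTUM = 1e-4

#: maximum number of image shells searched when enumerating periodic dimers
MAX_IMAGE_SHELLS = 8

PairPotential = Callable[[str, str, float], float]


class LedgerError(KeyError):
    """A fragment energy required for assembly is missing from the ledger."""


# ---------------------------------------------------------------------------
# canonical fragment keys
# ---------------------------------------------------------------------------

def _quantize(values: np.ndarray) -> tuple[int, ...]:
    return tuple(int(round(v / KEY_QUANTUM)) for v in np.sort(values))


def _digest(payload: str, prefix: str) -> str:
    return prefix + hashlib.sha1(payload.encode()).hexdigest()[:12]


def _molecule_descriptor(m: Molecule) -> tuple:
    if m.n_atoms == 1:
        return (tuple(sorted(m.atoms)), ())
    d = np.linalg.norm(m.coords[:, None, :] - m.coords[None, :, :], axis=-1)
    iu = np.triu_indices(m.n_atoms, k=1)
    return (tuple(sorted(m.atoms)), _quantize(d[iu]))


def monomer_key(m: Molecule) -> str:
    """Translation/rotation/ordering-invariant identifier of a monomer.

    Built from the element multiset and the quantized intramolecular distance
    spectrum, so symmetry-equivalent copies collapse to one key.
    """
    return _digest(repr(_molecule_descriptor(m)), "m")


def dimer_key(a: Molecule, b: Molecule) -> str:
    """Ordering-invariant identifier of a dimer geometry.

    Combines the two monomer descriptors (as an unordered pair) with the
    quantized intermolecular distance spectrum; (a, b, shift) and
    (b, a, −shift) therefore map to the same key.
    """
    inter = np.linalg.norm(a.coords[:, None, :] - b.coords[None, :, :], axis=-1)
    payload = repr((tuple(sorted([_molecule_descriptor(a), _molecule_descriptor(b)])),
                    _quantize(inter.ravel())))
    return _digest(payload, "d")


def closest_contact(a: Molecule, b: Molecule) -> float:
    """Minimum interatomic distance between two molecules (Å)."""
    d = np.linalg.norm(a.coords[:, None, :] - b.coords[None, :, :], axis=-1)
    return float(d.min())


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DimerInstance:
    """A symmetry/translation-unique periodic dimer with its per-cell weight."""

    monomer_a: int                  # molecule index in the reference cell
    monomer_b: int                  # molecule index of the image partner
    image_shift: tuple[int, int, int]
    closest_contact: float
    multiplicity: float             # per-cell count, double-counting resolved
    canonical_key: str
    key_a: str                      # ledger keys of the two monomers
    key_b: str

    def __post_init__(self) -> None:
        if self.closest_contact <= 0:
            raise ValueError("closest_contact must be positive")
        if self.multiplicity <= 0:
            raise ValueError("multiplicity must be positive")


@dataclass
class MonomerEntry:
    molecule: Molecule
    key: str
    multiplicity: int               # symmetry-equivalent copies per cell


@dataclass
class FragmentJobSet:
    """Monomers and unique periodic dimers up to a closest-contact cutoff."""

    monomers: list[MonomerEntry]
    dimers: list[DimerInstance]
    cutoff: float
    z_molecules: int
    source_tag: str = ""

    def total_dimer_multiplicity(self, max_contact: float | None = None) -> float:
        mc = self.cutoff if max_contact is None else max_contact
        return sum(d.multiplicity for d in self.dimers if d.closest_contact <= mc)

    def dimer_molecules(self, s: CrystalStructure, d: DimerInstance) -> tuple[Molecule, Molecule]:
        """Reconstruct the two molecules of a dimer instance in Cartesian space."""
        assert s.molecules is not None
        a = s.molecules[d.monomer_a]
        shift = np.array(d.image_shift, dtype=float) @ s.cell.lattice_matrix
        return a, s.molecules[d.monomer_b].translated(shift)


@dataclass
class EnergyLedger:
    """Per-fragment energies keyed by (canonical key, theory-level label)."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    periodic_low_level: dict[str, float] = field(default_factory=dict)

    def set(self, key: str, level: str, energy: float) -> None:
        self.entries[(key, level)] = float(energy)

    def get(self, key: str, level: str) -> float:
        try:
            return self.entries[(key, level)]
        except KeyError:
            raise LedgerError(f"no energy for fragment {key!r} at level {level!r}") from None

    def has(self, key: str, level: str) -> bool:
        return (key, level) in self.entries

    def set_periodic(self, level: str, energy: float) -> None:
        self.periodic_low_level[level] = float(energy)

    def get_periodic(self, level: str) -> float:
        try:
            return self.periodic_low_level[level]
        except KeyError:
            raise LedgerError(f"no periodic energy at level {level!r}") from None

    def interaction(self, d: DimerInstance, level: str) -> float:
        """2-body interaction: E(dimer) − E(monomer a) − E(monomer b)."""
        return (self.get(d.canonical_key, level)
                - self.get(d.key_a, level) - self.get(d.key_b, level))

    def levels(self) -> list[str]:
        return sorted({lvl for _, lvl in self.entries})

    # -- structured-text round trip --------------------------------------
    def to_yaml(self) -> str:
        energies: dict[str, dict[str, float]] = {}
        for (key, level), e in sorted(self.entries.items()):
            energies.setdefault(key, {})[level] = e
        return yaml.safe_dump(
            {"energies": energies, "periodic": dict(self.periodic_low_level)},
            sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "EnergyLedger":
        data = yaml.safe_load(text)
        led = cls()
        for key, by_level in (data.get("energies") or {}).items():
            for level, e in by_level.items():
                led.set(str(key), str(level), float(e))
        for level, e in (data.get("periodic") or {}).items():
            led.set_periodic(str(level), float(e))
        return led


@dataclass
class HMBIEnergy:
    """Assembled hybrid fragment energy per unit cell (Hartree)."""

    e1_high: float
    e2sr_high: float
    e2lr_low: float
    emb_low: float
    z_molecules: int
    high_level: str
    low_level: str
    lr_split: bool = False          # True if e2lr/emb were separated explicitly

    def __post_init__(self) -> None:
        if self.z_molecules < 1:
            raise ValueError("z_molecules must be >= 1")

    @property
    def total(self) -> float:
        return self.e1_high + self.e2sr_high + self.e2lr_low + self.emb_low

    @property
    def low_level_remainder(self) -> float:
        return self.e2lr_low + self.emb_low

    @property
    def per_molecule(self) -> float:
        return self.total / self.z_molecules

    @property
    def e1_per_molecule(self) -> float:
        return self.e1_high / self.z_molecules

    @property
    def inter_per_molecule(self) -> float:
        """Intermolecular part per molecule: SR 2-body + low-level remainder."""
        return (self.e2sr_high + self.low_level_remainder) / self.z_molecules

    def components_kjmol(self) -> dict[str, float]:
        return {
            "e1_high": self.e1_high * HARTREE_TO_KJMOL,
            "e2sr_high": self.e2sr_high * HARTREE_TO_KJMOL,
            "e2lr_low": self.e2lr_low * HARTREE_TO_KJMOL,
            "emb_low": self.emb_low * HARTREE_TO_KJMOL,
            "total": self.total * HARTREE_TO_KJMOL,
        }


# ---------------------------------------------------------------------------
# fragment enumeration
# ---------------------------------------------------------------------------

def _image_shell_bound(s: CrystalStructure, cutoff: float) -> int:
    diam = 0.0
    assert s.molecules is not None
    for m in s.molecules:
        if m.n_atoms > 1:
            d = np.linalg.norm(m.coords[:, None, :] - m.coords[None, :, :], axis=-1)
            diam = max(diam, float(d.max()))
    h = float(s.cell.perpendicular_heights().min())
    return int(math.ceil((cutoff + diam) / h)) + 1


def enumerate_fragments(s: CrystalStructure, cutoff: float = DEFAULT_SR_CUTOFF,
                        deduplicate: bool = True,
                        max_shells: int = MAX_IMAGE_SHELLS) -> FragmentJobSet:
    """Enumerate monomers and unique periodic dimers within a contact cutoff.

    Every pair (reference-cell molecule, molecule in any lattice image) whose
    closest interatomic contact is ≤ ``cutoff`` is collected; the symmetric
    double counting of (a, b, shift) / (b, a, −shift) is resolved by the
    canonical key, and equivalent copies accumulate into a per-cell
    multiplicity.  With ``deduplicate=False`` each instance is kept separately
    (multiplicity ½ each), which must assemble to the same totals — a
    verification mode.

    The result is deterministic: dimers sorted by (closest_contact, key).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if s.molecules is None:
        perceive_molecules(s)
    assert s.molecules is not None and s.z_molecules is not None
    mols = s.molecules
    lat = s.cell.lattice_matrix

    nsh = _image_shell_bound(s, cutoff)
    if nsh > max_shells:
        raise ValueError(
            f"cutoff {cutoff} Å needs {nsh} image shells (> bound {max_shells}); "
            "raise max_shells for very small cells or large cutoffs")

    # symmetry-unique monomers with multiplicity
    mono_keys = [monomer_key(m) for m in mols]
    monomers: list[MonomerEntry] = []
    seen: dict[str, MonomerEntry] = {}
    for m, k in zip(mols, mono_keys):
        if k in seen:
            seen[k].multiplicity += 1
        else:
            entry = MonomerEntry(m, k, 1)
            seen[k] = entry
            monomers.append(entry)

    shifts = [np.array(t) for t in itertools.product(range(-nsh, nsh + 1), repeat=3)]
    groups: dict[str, list[tuple[float, int, int, tuple[int, int, int]]]] = {}
    for i, a in enumerate(mols):
        for j, b in enumerate(mols):
            for t in shifts:
                if i == j and not t.any():
                    continue
                bt = b.translated(t.astype(float) @ lat)
                cc = closest_contact(a, bt)
                if cc <= cutoff:
                    key = dimer_key(a, bt)
                    groups.setdefault(key, []).append(
                        (cc, i, j, (int(t[0]), int(t[1]), int(t[2]))))

    dimers: list[DimerInstance] = []
    for key, inst in groups.items():
        inst.sort()
        if deduplicate:
            cc, i, j, t = inst[0]
            dimers.append(DimerInstance(i, j, t, cc, len(inst) / 2.0, key,
                                        mono_keys[i], mono_keys[j]))
        else:
            for cc, i, j, t in inst:
                dimers.append(DimerInstance(i, j, t, cc, 0.5, key,
                                            mono_keys[i], mono_keys[j]))
    dimers.sort(key=lambda d: (d.closest_contact, d.canonical_key,
                               d.monomer_a, d.monomer_b, d.image_shift))
    return FragmentJobSet(monomers=monomers, dimers=dimers, cutoff=cutoff,
                          z_molecules=s.z_molecules, source_tag=s.tag)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_hmbi(jobs: FragmentJobSet, ledger: EnergyLedger,
                  high: str, low: str,
                  sr_cutoff: float | None = None) -> HMBIEnergy:
    """Assemble the hybrid fragment energy per unit cell.

    Dimers with closest contact ≤ ``sr_cutoff`` (default: the enumeration
    cutoff) contribute their high-level 2-body interactions; the low-level
    remainder is computed robustly by difference against the periodic
    low-level energy,

        remainder = E_periodic(low) − ΣE1(low) − ΣE2_SR(low),

    and split into an explicit long-range 2-body part and a many-body part
    whenever the job set contains dimers beyond ``sr_cutoff`` with low-level
    ledger entries.  The identity total = e1 + e2sr + e2lr + emb holds exactly
    by construction.
    """
    sr = jobs.cutoff if sr_cutoff is None else sr_cutoff
    if sr > jobs.cutoff + 1e-12:
        raise ValueError("sr_cutoff cannot exceed the enumeration cutoff")

    e1_high = sum(mo.multiplicity * ledger.get(mo.key, high) for mo in jobs.monomers)
    e1_low = sum(mo.multiplicity * ledger.get(mo.key, low) for mo in jobs.monomers)

    sr_dimers = [d for d in jobs.dimers if d.closest_contact <= sr]
    lr_dimers = [d for d in jobs.dimers if d.closest_contact > sr]

    e2sr_high = sum(d.multiplicity * ledger.interaction(d, high) for d in sr_dimers)
    e2sr_low = sum(d.multiplicity * ledger.interaction(d, low) for d in sr_dimers)

    periodic_low = ledger.get_periodic(low)
    remainder = periodic_low - e1_low - e2sr_low

    lr_split = bool(lr_dimers) and all(
        ledger.has(d.canonical_key, low) for d in lr_dimers)
    if lr_split:
        e2lr_low = sum(d.multiplicity * ledger.interaction(d, low) for d in lr_dimers)
        emb_low = remainder - e2lr_low
    else:
        e2lr_low = remainder
        emb_low = 0.0
    return HMBIEnergy(e1_high=e1_high, e2sr_high=e2sr_high, e2lr_low=e2lr_low,
                      emb_low=emb_low, z_molecules=jobs.z_molecules,
                      high_level=high, low_level=low, lr_split=lr_split)


def per_molecule_lattice_energy(h: HMBIEnergy, gas_reference: float) -> float:
    """Lattice energy per molecule in kJ mol⁻¹, relative to the gas phase.

    ``gas_reference`` is the isolated-molecule energy (Hartree) at the same
    high level as the 1-body terms; the result is negative for a bound
    crystal.
    """
    return (h.per_molecule - gas_reference) * HARTREE_TO_KJMOL


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def molecule_pair_energy(a: Molecule, b: Molecule, potential: PairPotential) -> float:
    """Sum of atom-pair energies between two molecules (Hartree)."""
    total = 0.0
    for ea, ra in zip(a.atoms, a.coords):
        for eb, rb in zip(b.atoms, b.coords):
            r = float(np.linalg.norm(ra - rb))
            if r <= 0:
                raise ValueError("overlapping atoms: non-finite pair energy")
            e = potential(ea, eb, r)
            if not math.isfinite(e):
                raise ValueError("non-finite pair energy")
            total += e
    return total


def intramolecular_energy(m: Molecule, potential: PairPotential) -> float:
    """Sum of atom-pair energies inside one molecule (Hartree)."""
    total = 0.0
    for i in range(m.n_atoms):
        for j in range(i + 1, m.n_atoms):
            r = float(np.linalg.norm(m.coords[i] - m.coords[j]))
            if r <= 0:
                raise ValueError("overlapping atoms: non-finite pair energy")
            total += potential(m.atoms[i], m.atoms[j], r)
    return total


def brute_force_lattice_sum(s: CrystalStructure, potential: PairPotential,
                            shell_radius: float,
                            max_shells: int = MAX_IMAGE_SHELLS) -> float:
    """Direct pairwise intermolecular lattice sum per unit cell (Hartree).

    Sums the full pair energy for every (reference-cell molecule, image
    molecule) pair whose closest interatomic contact is ≤ ``shell_radius``,
    halved for double counting.  Deliberately a plain double loop, independent
    of the fragment enumeration, so it can serve as the oracle for the
    many-body-expansion bookkeeping.
    """
    if s.molecules is None:
        perceive_molecules(s)
    assert s.molecules is not None
    mols = s.molecules
    lat = s.cell.lattice_matrix
    nsh = _image_shell_bound(s, shell_radius)
    if nsh > max_shells:
        raise ValueError(f"shell_radius needs {nsh} image shells (> {max_shells})")
    total = 0.0
    for i, a in enumerate(mols):
        for j, b in enumerate(mols):
            for t in itertools.product(range(-nsh, nsh + 1), repeat=3):
                if i == j and t == (0, 0, 0):
                    continue
                bt = b.translated(np.array(t, dtype=float) @ lat)
                if closest_contact(a, bt) <= shell_radius:
                    total += molecule_pair_energy(a, bt, potential)
    return total / 2.0


# ---------------------------------------------------------------------------
# fragment export
# ---------------------------------------------------------------------------

def export_fragments(jobs: FragmentJobSet, s: CrystalStructure) -> dict[str, str]:
    """Render each unique fragment as an XYZ block plus a manifest.

    Returns a mapping filename → file text; keys are ``<key>.xyz`` for each
    fragment and ``manifest.yaml`` describing id, type, multiplicity and
    closest contact.
    """
    from .crystal_io import write_xyz

    files: dict[str, str] = {}
    manifest: dict[str, dict] = {}
    for mo in jobs.monomers:
        files[f"{mo.key}.xyz"] = write_xyz(mo.molecule.atoms, mo.molecule.coords,
                                           comment=mo.key)
        manifest[mo.key] = {"type": "monomer", "multiplicity": mo.multiplicity}
    for d in jobs.dimers:
        if f"{d.canonical_key}.xyz" in files:
            continue
        a, b = jobs.dimer_molecules(s, d)
        files[f"{d.canonical_key}.xyz"] = write_xyz(
            a.atoms + b.atoms, np.vstack([a.coords, b.coords]), comment=d.canonical_key)
        manifest[d.canonical_key] = {
            "type": "dimer", "multiplicity": d.multiplicity,
            "closest_contact": round(d.closest_contact, 6),
            "monomers": [d.key_a, d.key_b],
        }
    files["manifest.yaml"] = yaml.safe_dump(manifest, sort_keys=True)
    return files
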