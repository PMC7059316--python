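"""Self-contained synthetic inputs for exercising the whole pipeline.

Generates toy molecular crystals with a Lennard-Jones surrogate pair
potential (standing in for the quantum-chemistry engines behind the energy
ledgers), engineered conformational-polymorph pairs whose intra/inter
decomposition is known exactly, synthetic frequency sets, and basis-cardinal
energy series of exactly the X⁻³ form the CBS extrapolation assumes.  Every
generator is deterministic under its seed.  These fixtures validate
bookkeeping and arithmetic, not chemistry: the toy molecules are rigid 1–3
atom species, and conformational effects are injected through the ledger's
1-body energies rather than actual torsions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .crystal_io import (HARTREE_TO_KJMOL, AtomSite, CrystalStructure,
                         TAG_RELAXED_0K, UnitCell, perceive_molecules)
from .energetics import BasisSeriesPoint
from .fragmentation import (EnergyLedger, FragmentJobSet, PairPotential,
                            brute_force_lattice_sum, enumerate_fragments,
                            intramolecular_energy, molecule_pair_energy)
from .thermochem import FrequencySet

#: default surrogate level label used for both the "high" and "low" sides
TOY_LEVEL = "LJ"


@dataclass
class ToyPotentialSpec:
    """Lennard-Jones surrogate: E = 4ε[(σ/r)¹² − (σ/r)⁶] per element pair.

    ε in Hartree, σ in Å; ``pair_table`` maps sorted element pairs to (ε, σ).
    Missing pairs combine by Lorentz–Berthelot rules from the homonuclear
    entries.
    """

    pair_table: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("Ar", "Ar"): (4.0e-4, 3.4),
            ("Ne", "Ne"): (1.2e-4, 2.8),
        })
    charges: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for pair, (eps, sigma) in self.pair_table.items():
            if eps <= 0 or sigma <= 0:
                raise ValueError(f"ε and σ must be positive for {pair}")

    def epsilon_sigma(self, a: str, b: str) -> tuple[float, float]:
        key = tuple(sorted((a, b)))
        if key in self.pair_table:
            return self.pair_table[key]
        ea, sa = self.pair_table[(a, a)]
        eb, sb = self.pair_table[(b, b)]
        return float(np.sqrt(ea * eb)), 0.5 * (sa + sb)

    def potential(self) -> PairPotential:
        def lj(el_a: str, el_b: str, r: float) -> float:
            eps, sigma = self.epsilon_sigma(el_a, el_b)
            sr6 = (sigma / r) ** 6
            return 4.0 * eps * (sr6 * sr6 - sr6)
        return lj


def ledger_from_potential(s: CrystalStructure, spec: ToyPotentialSpec,
                          cutoff: float, level: str = TOY_LEVEL,
                          jobs: FragmentJobSet | None = None) -> EnergyLedger:
    """Evaluate every fragment of a structure under the toy potential.

    Writes monomer energies (intramolecular pair sum), dimer total energies,
    and the periodic energy per cell — ΣE_monomer plus the brute-force
    intermolecular lattice sum truncated at ``cutoff`` — all under one level
    label, so the hybrid assembly with high = low must reproduce the lattice
    sum exactly and show a vanishing many-body term.
    """
    pot = spec.potential()
    if jobs is None:
        jobs = enumerate_fragments(s, cutoff=cutoff)
    ledger = EnergyLedger()
    for mo in jobs.monomers:
        ledger.set(mo.key, level, intramolecular_energy(mo.molecule, pot))
    for d in jobs.dimers:
        a, b = jobs.dimer_molecules(s, d)
        e = (intramolecular_energy(a, pot) + intramolecular_energy(b, pot)
             + molecule_pair_energy(a, b, pot))
        ledger.set(d.canonical_key, level, e)
    e1 = sum(mo.multiplicity * ledger.get(mo.key, level) for mo in jobs.monomers)
    ledger.set_periodic(level, e1 + brute_force_lattice_sum(s, pot, cutoff))
    return ledger


def make_toy_crystal(spec: ToyPotentialSpec, molecules_per_cell: int = 1,
                     noise: float = 0.0, a: float = 6.0,
                     diatomic: bool = True, bond_length: float = 1.1,
                     cutoff: float = 9.0, max_retries: int = 20,
                     ) -> tuple[CrystalStructure, EnergyLedger, FragmentJobSet]:
    """A periodic packing of small rigid molecules plus its exact toy ledger.

    Molecules (monatomic Ar or Ar₂ diatomics) are placed on a deterministic
    sublattice of a cubic cell of edge ``a`` Å, jittered by uniform noise of
    the given amplitude; placements with interatomic contacts closer than
    1.5 Å are regenerated up to ``max_retries`` times.
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    if molecules_per_cell < 1:
        raise ValueError("molecules_per_cell must be >= 1")
    rng = np.random.default_rng(spec.seed)
    lat = np.eye(3) * a
    # deterministic fractional anchors: spread along the cell diagonal
    anchors = [np.full(3, (k / molecules_per_cell + 0.1) % 1.0)
               for k in range(molecules_per_cell)]
    min_contact = 2.0  # Å, intermolecular clash threshold
    for _attempt in range(max_retries):
        sites: list[AtomSite] = []
        for k, anchor in enumerate(anchors):
            jitter = rng.uniform(-noise, noise, size=3) / a
            base = (anchor + jitter) % 1.0
            if diatomic:
                offset = np.array([bond_length / a, 0.0, 0.0])
                sites.append(AtomSite("Ar", base, f"Ar{2*k+1}"))
                sites.append(AtomSite("Ar", (base + offset) % 1.0, f"Ar{2*k+2}"))
            else:
                sites.append(AtomSite("Ar", base, f"Ar{k+1}"))
        s = CrystalStructure(cell=UnitCell(lat), sites=sites, tag=TAG_RELAXED_0K)
        try:
            mols = perceive_molecules(s)
        except ValueError:
            continue
        if len(mols) != molecules_per_cell:
            continue
        # intermolecular clash check across the cell and first image shell
        ok = True
        for i, ma in enumerate(mols):
            for j, mb in enumerate(mols):
                for t in itertools.product((-1, 0, 1), repeat=3):
                    if i == j and t == (0, 0, 0):
                        continue
                    shifted = mb.translated(np.array(t, dtype=float) @ lat)
                    d = np.linalg.norm(
                        ma.coords[:, None, :] - shifted.coords[None, :, :], axis=-1)
                    if d.min() < min_contact:
                        ok = False
        if ok:
            break
    else:
        raise RuntimeError("could not place molecules without overlaps")
    jobs = enumerate_fragments(s, cutoff=cutoff)
    ledger = ledger_from_potential(s, spec, cutoff, jobs=jobs)
    return s, ledger, jobs


def make_polymorph_pair(spec: ToyPotentialSpec,
                        conformational_penalty: float = 5.0,
                        packing_gain: float = 6.0,
                        cutoff: float = 9.0,
                        ) -> dict[str, tuple[CrystalStructure, EnergyLedger, FragmentJobSet]]:
    """Two engineered 'polymorphs' with a known intra/inter decomposition.

    Polymorph A is a plain toy crystal.  Polymorph B shares its geometry but
    its ledger encodes the conformational-polymorph trade-off: every 1-body
    energy is raised by ``conformational_penalty`` (kJ mol⁻¹ per molecule, the
    cost of abandoning the favorable conformation) while the pairwise
    intermolecular energy is lowered by ``packing_gain`` per molecule (the
    better packing it buys).  The decomposition must recover
    ΔE_intra = +penalty, ΔE_inter = −gain, ΔE_lattice = penalty − gain
    exactly.  Ledgers are kept per polymorph, as they would be for real
    fragment jobs.
    """
    if conformational_penalty < 0 or packing_gain < 0:
        raise ValueError("penalty and gain must be non-negative")
    s_a, led_a, jobs_a = make_toy_crystal(spec, molecules_per_cell=2,
                                          noise=0.0, a=7.0, cutoff=cutoff)
    level = TOY_LEVEL
    z = jobs_a.z_molecules
    pen = conformational_penalty / HARTREE_TO_KJMOL
    gain = packing_gain / HARTREE_TO_KJMOL

    led_b = EnergyLedger()
    # 1-body: every monomer pays the conformational penalty
    for mo in jobs_a.monomers:
        led_b.set(mo.key, level, led_a.get(mo.key, level) + pen)
    # 2-body: dimer totals shift by the two monomer penalties, and the cell's
    # pairwise interaction drops by z·gain spread over the dimer multiplicities
    total_mult = sum(d.multiplicity for d in jobs_a.dimers)
    if total_mult <= 0:
        raise RuntimeError("polymorph fixture needs at least one dimer in range")
    per_dimer_gain = z * gain / total_mult
    for d in jobs_a.dimers:
        led_b.set(d.canonical_key, level,
                  led_a.get(d.canonical_key, level) + 2.0 * pen - per_dimer_gain)
    led_b.set_periodic(level, led_a.get_periodic(level) + z * pen - z * gain)

    return {"A": (s_a, led_a, jobs_a), "B": (s_a, led_b, jobs_a)}


def make_synthetic_series(e_cbs: float, amplitude: float,
                          cardinals: list[int],
                          e_hf: float = -1.0) -> list[BasisSeriesPoint]:
    """Basis series with correlation energy exactly e_cbs + amplitude·X⁻³."""
    if any(x < 2 for x in cardinals):
        raise ValueError("basis cardinals must be >= 2")
    return [BasisSeriesPoint(cardinal=x, e_hf=e_hf,
                             e_corr=e_cbs + amplitude * x ** -3.0)
            for x in cardinals]


def make_frequency_set(n_modes: int, lo: float = 30.0, hi: float = 3000.0,
                       seed: int = 0, z_molecules: int = 1,
                       structure_tag: str = TAG_RELAXED_0K) -> FrequencySet:
    """Uniformly distributed positive mode list (cm⁻¹), seeded."""
    if n_modes < 1:
        raise ValueError("need at least one mode")
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    rng = np.random.default_rng(seed)
    return FrequencySet(np.sort(rng.uniform(lo, hi, size=n_modes)),
                        z_molecules=z_molecules, structure_tag=structure_tag)
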