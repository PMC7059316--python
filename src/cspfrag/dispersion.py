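"""Pairwise C6/C8 dispersion with coordination-number-interpolated coefficients.

Implements the D3-style machinery: a smooth coordination number (CN) per atom,
Gaussian-weighted interpolation of reference C6 coefficients over CN pairs,
the C8 recursion C8 = 3·C6·√(Q_a·Q_b), and damped −C6/R⁶ − C8/R⁸ pair
energies.  A dispersion *correction* of the MP2D kind is the difference of two
such sums evaluated with two coefficient flavors — one describing the accurate
(coupled Kohn–Sham) response and one the uncoupled-Hartree–Fock-like response
already implicit in MP2 — partitioned into intra- and intermolecular parts.

The engine is unit-agnostic in the coefficients: with C6 in (kJ mol⁻¹)·Å⁶ and
C8 in (kJ mol⁻¹)·Å⁸ the energies come out in kJ mol⁻¹.  The global empirical
parameters (damping vector, R⁻⁸ scaling) are not hard-coded; they load from a
structured data file, and a small synthetic table ships for testing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .crystal_io import Molecule, covalent_radius

logger = logging.getLogger("cspfrag")

#: D3-style CN counting-function constants
DEFAULT_K1 = 16.0
DEFAULT_K2 = 4.0 / 3.0
#: Gaussian interpolation width for the C6 reference weighting
DEFAULT_K3 = 4.0

_FACTORIALS = [math.factorial(k) for k in range(9)]


@dataclass
class DispersionParams:
    """Constants and reference tables for the pair dispersion model.

    ``reference_table[flavor][(el_a, el_b)]`` is a list of reference points
    ``(cn_a, cn_b, c6)`` with elements in sorted order; ``q_factors`` feed the
    C8 recursion; ``damping`` holds the family label ("tang-toennies" or
    "becke-johnson") and its parameter vector — this is where a model's global
    empirical parameters live.
    """

    cn_constants: dict[str, float] = field(
        default_factory=lambda: {"k1": DEFAULT_K1, "k2": DEFAULT_K2, "k3": DEFAULT_K3})
    reference_table: dict[str, dict[tuple[str, str], list[tuple[float, float, float]]]] = \
        field(default_factory=dict)
    q_factors: dict[str, float] = field(default_factory=dict)
    damping: dict = field(default_factory=lambda: {
        "family": "tang-toennies", "params": {"b": 3.0, "s6": 1.0, "s8": 1.0}})
    covalent_radii: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for flavor, table in self.reference_table.items():
            for pair, refs in table.items():
                if any(c6 < 0 for _, _, c6 in refs):
                    raise ValueError(f"negative reference C6 for {pair} ({flavor})")
        if any(q <= 0 for q in self.q_factors.values()):
            raise ValueError("Q factors must be positive")
        for v in self.damping.get("params", {}).values():
            if not math.isfinite(float(v)):
                raise ValueError("damping parameters must be finite")
        flavors = list(self.reference_table)
        if len(flavors) >= 2:
            sets = [set(self.reference_table[f]) for f in flavors]
            if any(s != sets[0] for s in sets[1:]):
                raise ValueError("coefficient flavors must cover the same element pairs")

    def radius(self, element: str) -> float:
        if element in self.covalent_radii:
            return self.covalent_radii[element]
        return covalent_radius(element)

    @classmethod
    def from_dict(cls, data: dict) -> "DispersionParams":
        table: dict[str, dict[tuple[str, str], list[tuple[float, float, float]]]] = {}
        for flavor, pairs in (data.get("reference_table") or {}).items():
            table[flavor] = {}
            for pair_label, refs in pairs.items():
                a, b = pair_label.split("-")
                key = tuple(sorted((a, b)))
                table[flavor][key] = [tuple(map(float, r)) for r in refs]
        cn = {"k1": DEFAULT_K1, "k2": DEFAULT_K2, "k3": DEFAULT_K3}
        cn.update({k: float(v) for k, v in (data.get("cn_constants") or {}).items()})
        return cls(
            cn_constants=cn,
            reference_table=table,
            q_factors={k: float(v) for k, v in (data.get("q_factors") or {}).items()},
            damping=data.get("damping") or
            {"family": "tang-toennies", "params": {"b": 3.0, "s6": 1.0, "s8": 1.0}},
            covalent_radii={k: float(v) for k, v in
                            (data.get("covalent_radii") or {}).items()},
        )

    @classmethod
    def from_yaml(cls, text: str) -> "DispersionParams":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def synthetic(cls) -> "DispersionParams":
        """The synthetic test table shipped with the package."""
        text = resources.files("cspfrag").joinpath(
            "data/synthetic_dispersion_params.yaml").read_text()
        return cls.from_yaml(text)


@dataclass
class DispersionResult:
    """A pair-dispersion sum split by molecule membership (kJ mol⁻¹)."""

    intra_part: float
    inter_part: float
    per_pair: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def total(self) -> float:
        return self.intra_part + self.inter_part


# ---------------------------------------------------------------------------
# coordination numbers
# ---------------------------------------------------------------------------

def _gather(geometry: Molecule | Sequence[Molecule]) -> tuple[list[str], np.ndarray, np.ndarray]:
    mols = [geometry] if isinstance(geometry, Molecule) else list(geometry)
    atoms = [el for m in mols for el in m.atoms]
    coords = np.vstack([m.coords for m in mols]) if mols else np.zeros((0, 3))
    mol_id = np.concatenate([np.full(m.n_atoms, i) for i, m in enumerate(mols)]) \
        if mols else np.zeros(0, dtype=int)
    return atoms, coords, mol_id


def coordination_numbers(geometry: Molecule | Sequence[Molecule],
                         p: DispersionParams) -> np.ndarray:
    """Smooth per-atom coordination numbers.

    CN_a = Σ_{b≠a} 1 / (1 + exp(−k1·(k2·(r_cov,a + r_cov,b)/R_ab − 1))),
    a logistic count that tends to the integer bond count for well-separated
    structures and varies smoothly with geometry.
    """
    atoms, coords, _ = _gather(geometry)
    k1 = p.cn_constants["k1"]
    k2 = p.cn_constants["k2"]
    radii = np.array([p.radius(el) for el in atoms])
    n = len(atoms)
    cn = np.zeros(n)
    if n < 2:
        return cn
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    if np.any(d[~np.eye(n, dtype=bool)] <= 0):
        raise ValueError("zero interatomic distance in CN evaluation")
    rsum = radii[:, None] + radii[None, :]
    with np.errstate(over="ignore"):
        counts = 1.0 / (1.0 + np.exp(-k1 * (k2 * rsum / np.where(d > 0, d, 1.0) - 1.0)))
    np.fill_diagonal(counts, 0.0)
    return counts.sum(axis=1)


# ---------------------------------------------------------------------------
# coefficients
# ---------------------------------------------------------------------------

def pair_coefficients(elem_a: str, elem_b: str, cn_a: float, cn_b: float,
                      flavor: str, p: DispersionParams) -> tuple[float, float]:
    """CN-interpolated (C6, C8) for an element pair under one flavor.

    C6 is the Gaussian-weighted average of the reference values, with weights
    exp(−k3·[(CN_a−CN_a,ref)² + (CN_b−CN_b,ref)²]); C8 follows from the
    recursion C8 = 3·C6·√(Q_a·Q_b).  The interpolated C6 always lies within
    the [min, max] range of the references for the pair.
    """
    try:
        table = p.reference_table[flavor]
    except KeyError:
        raise KeyError(f"unknown coefficient flavor {flavor!r}") from None
    key = tuple(sorted((elem_a, elem_b)))
    if key not in table:
        raise KeyError(f"no reference C6 for pair {elem_a}-{elem_b} (flavor {flavor!r})")
    refs = table[key]
    # reference CN ordering follows the sorted element pair
    if key != (elem_a, elem_b):
        cn_a, cn_b = cn_b, cn_a
    k3 = p.cn_constants["k3"]
    num = den = 0.0
    for ra, rb, c6ref in refs:
        w = math.exp(-k3 * ((cn_a - ra) ** 2 + (cn_b - rb) ** 2))
        num += w * c6ref
        den += w
    if den <= 0.0:
        # all weights underflowed: fall back to the nearest reference point
        dists = [((cn_a - ra) ** 2 + (cn_b - rb) ** 2, c6ref) for ra, rb, c6ref in refs]
        c6 = min(dists)[1]
    else:
        c6 = num / den
    for el in (elem_a, elem_b):
        if el not in p.q_factors:
            raise KeyError(f"no Q factor for element {el}")
    c8 = 3.0 * c6 * math.sqrt(p.q_factors[elem_a] * p.q_factors[elem_b])
    return c6, c8


# ---------------------------------------------------------------------------
# damping and pair energies
# ---------------------------------------------------------------------------

def _tang_toennies(n: int, br: float) -> float:
    """f_n(R) = 1 − exp(−bR)·Σ_{k≤n}(bR)^k/k!  — complete in the limits:
    → 1 for bR → ∞ and → 0 like (bR)^{n+1} for bR → 0.

    For small bR the subtraction cancels catastrophically, so the equivalent
    tail series exp(−bR)·Σ_{k>n}(bR)^k/k! is used there instead.
    """
    if br > 35.0:
        return 1.0
    if br < 1.0:
        term = br ** (n + 1) / math.factorial(n + 1)
        tail = 0.0
        k = n + 1
        while term > 1e-300:
            tail += term
            k += 1
            term *= br / k
            if term < tail * 1e-18:
                tail += term
                break
        return math.exp(-br) * tail
    s = sum(br ** k / _FACTORIALS[k] for k in range(n + 1))
    return 1.0 - math.exp(-br) * s


def damped_pair_energy(r: float, c6: float, c8: float, p: DispersionParams) -> float:
    """Damped dispersion energy of one atom pair at separation ``r`` (Å).

    E = −[s6·f6(R)·C6/R⁶ + s8·f8(R)·C8/R⁸]; the damping functions approach 1
    at large R (undamped asymptote) and suppress the divergence at short R
    (E → 0 under Tang–Toennies damping).
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if c6 < 0 or c8 < 0:
        raise ValueError("dispersion coefficients must be non-negative")
    family = p.damping.get("family", "tang-toennies")
    prm = p.damping.get("params", {})
    s6 = float(prm.get("s6", 1.0))
    s8 = float(prm.get("s8", 1.0))
    if family == "tang-toennies":
        b = float(prm.get("b", 3.0))
        f6 = _tang_toennies(6, b * r)
        f8 = _tang_toennies(8, b * r)
        return -(s6 * f6 * c6 / r ** 6 + s8 * f8 * c8 / r ** 8)
    if family == "becke-johnson":
        a1 = float(prm.get("a1", 0.4))
        a2 = float(prm.get("a2", 2.0))
        r0 = math.sqrt(c8 / c6) if c6 > 0 else a2
        rd = a1 * r0 + a2
        return -(s6 * c6 / (r ** 6 + rd ** 6) + s8 * c8 / (r ** 8 + rd ** 8))
    raise ValueError(f"unknown damping family {family!r}")


def _flavor_sum(atoms: list[str], coords: np.ndarray, mol_id: np.ndarray,
                cn: np.ndarray, flavor: str,
                p: DispersionParams) -> DispersionResult:
    n = len(atoms)
    intra = inter = 0.0
    per_pair: list[tuple[int, int, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            c6, c8 = pair_coefficients(atoms[i], atoms[j], cn[i], cn[j], flavor, p)
            e = damped_pair_energy(r, c6, c8, p)
            per_pair.append((i, j, e))
            if mol_id[i] == mol_id[j]:
                intra += e
            else:
                inter += e
    return DispersionResult(intra_part=intra, inter_part=inter, per_pair=per_pair)


def dispersion_energy(geometry: Molecule | Sequence[Molecule], flavor: str,
                      p: DispersionParams) -> DispersionResult:
    """Full damped pair-dispersion sum for one coefficient flavor (kJ mol⁻¹)."""
    atoms, coords, mol_id = _gather(geometry)
    if len(atoms) < 2:
        logger.warning("dispersion requested for < 2 atoms; returning zero")
        return DispersionResult(0.0, 0.0)
    cn = coordination_numbers(geometry, p)
    return _flavor_sum(atoms, coords, mol_id, cn, flavor, p)


def dispersion_correction(geometry: Molecule | Sequence[Molecule],
                          p: DispersionParams,
                          flavor_accurate: str = "cks",
                          flavor_baseline: str = "uchf") -> DispersionResult:
    """Difference-of-flavors dispersion correction (kJ mol⁻¹).

    correction = E_disp(accurate) − E_disp(baseline); the baseline flavor
    represents the dispersion already contained in the underlying correlation
    treatment, so identical tables give an identically zero correction.  The
    result is partitioned into intra- and intermolecular parts, which is the
    point: the correction fixes conformational (intramolecular) and packing
    (intermolecular) dispersion on the same footing.
    """
    atoms, coords, mol_id = _gather(geometry)
    if len(atoms) < 2:
        logger.warning("dispersion correction for < 2 atoms is identically zero")
        return DispersionResult(0.0, 0.0)
    cn = coordination_numbers(geometry, p)
    acc = _flavor_sum(atoms, coords, mol_id, cn, flavor_accurate, p)
    base = _flavor_sum(atoms, coords, mol_id, cn, flavor_baseline, p)
    per_pair = [(i, j, ea - eb) for (i, j, ea), (_, _, eb)
                in zip(acc.per_pair, base.per_pair)]
    return DispersionResult(intra_part=acc.intra_part - base.intra_part,
                            inter_part=acc.inter_part - base.inter_part,
                            per_pair=per_pair)


def apply_correction_to_ledger(ledger, corrections: dict[str, float],
                               base_level: str = "MP2",
                               corrected_level: str = "MP2D") -> None:
    """Add per-fragment corrections (Hartree) to base-level ledger energies,
    writing them back under the corrected level label."""
    for key, de in corrections.items():
        ledger.set(key, corrected_level, ledger.get(key, base_level) + de)
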