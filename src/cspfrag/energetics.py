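"""Basis-set protocols, composite energies, and stability decomposition.

Two-point complete-basis-set (CBS) extrapolation of the correlation energy
(X⁻³ form, mean-field energy taken at the larger basis), the delta-CCSD(T)
composite, the decomposition of relative polymorph stabilities into
intramolecular (1-body), pairwise intermolecular, and many-body parts, and
root-mean-square dimer-error statistics against a reference level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crystal_io import HARTREE_TO_KJMOL
from .fragmentation import HMBIEnergy

#: Table-style column order for stability reports (kJ mol⁻¹ per molecule)
STABILITY_COLUMNS = ["dE_intra", "dE_inter", "dE_lattice",
                     "dH_0K", "dH_298K", "dH_ext", "dG_298K"]


@dataclass(frozen=True)
class BasisSeriesPoint:
    """Energies at one basis-set cardinal number X (Hartree)."""

    cardinal: int
    e_hf: float
    e_corr: float

    def __post_init__(self) -> None:
        if self.cardinal < 2:
            raise ValueError("basis cardinal must be >= 2")


def cbs_extrapolate(p_small: BasisSeriesPoint, p_large: BasisSeriesPoint,
                    exponent: float = 3.0) -> float:
    """Two-point CBS total energy (Hartree).

    The correlation energy is extrapolated assuming E_corr(X) = E_CBS + A·X⁻ⁿ
    (n = 3 by default), giving

        E_corr,CBS = (Y^n·e_corr,Y − X^n·e_corr,X) / (Y^n − X^n),

    and the mean-field energy is *not* extrapolated: the total is
    e_hf(larger basis) + E_corr,CBS.  The standard pairing is X = 3, 4
    (aug-cc-pVTZ / aug-cc-pVQZ), but any distinct cardinals work and recover
    the planted limit exactly for a series of that form.
    """
    if p_small.cardinal == p_large.cardinal:
        raise ValueError("cardinals must differ")
    if p_large.cardinal < p_small.cardinal:
        p_small, p_large = p_large, p_small
    x, y = float(p_small.cardinal), float(p_large.cardinal)
    xn, yn = x ** exponent, y ** exponent
    e_corr_cbs = (yn * p_large.e_corr - xn * p_small.e_corr) / (yn - xn)
    return p_large.e_hf + e_corr_cbs


def ccsdt_composite(e_mp2_cbs: float, e_ccsdt_small: float,
                    e_mp2_small: float) -> float:
    """Delta-corrected coupled-cluster composite (Hartree).

    CCSD(T)/CBS ≈ MP2/CBS + [CCSD(T) − MP2] evaluated in a common small
    basis on the same geometry.  Being additive, the correction commutes with
    the linear fragment assembly: correcting per fragment and assembling, or
    assembling and correcting the totals, give identical results.
    """
    for e in (e_mp2_cbs, e_ccsdt_small, e_mp2_small):
        if not np.isfinite(e):
            raise ValueError("non-finite energy in composite")
    return e_mp2_cbs + (e_ccsdt_small - e_mp2_small)


# ---------------------------------------------------------------------------
# stability decomposition
# ---------------------------------------------------------------------------

@dataclass
class StabilityTable:
    """Relative polymorph energetics versus a named reference form.

    All values in kJ mol⁻¹ per molecule; the reference row is identically
    zero, and dE_intra + dE_inter = dE_lattice by construction.  The optional
    ``dE_many_body`` column reports the many-body part separately; it is
    *also* folded into dE_inter, mirroring the convention of decomposition
    tables that fold everything intermolecular together.
    """

    reference_polymorph: str
    frame: pd.DataFrame

    def row(self, polymorph: str) -> pd.Series:
        return self.frame.loc[polymorph]

    def to_csv(self) -> str:
        return self.frame.to_csv(index_label="polymorph", float_format="%.6f")


def decompose_stabilities(entries: Mapping[str, HMBIEnergy], reference: str,
                          formulas: Mapping[str, str] | None = None) -> StabilityTable:
    """Decompose relative lattice energies into intra/inter(/many-body) parts.

    For each polymorph, the intramolecular column is the per-molecule 1-body
    sum minus the reference's; the intermolecular column collects the
    pairwise 2-body terms plus the low-level remainder (long-range 2-body +
    many-body); their sum is the relative lattice energy.  All entries must
    be assembled at identical theory levels (and, when formulas are supplied,
    must describe the same molecule).
    """
    if reference not in entries:
        raise KeyError(f"reference polymorph {reference!r} not among entries")
    levels = {(h.high_level, h.low_level) for h in entries.values()}
    if len(levels) > 1:
        raise ValueError(f"mixed theory levels across polymorphs: {sorted(levels)}")
    if formulas:
        if len(set(formulas.values())) > 1:
            raise ValueError("polymorphs have differing molecular formulas")

    ref = entries[reference]
    rows = {}
    any_split = any(h.lr_split for h in entries.values())
    for name, h in sorted(entries.items()):
        de_intra = (h.e1_per_molecule - ref.e1_per_molecule) * HARTREE_TO_KJMOL
        de_inter = (h.inter_per_molecule - ref.inter_per_molecule) * HARTREE_TO_KJMOL
        row = {"dE_intra": de_intra, "dE_inter": de_inter,
               "dE_lattice": de_intra + de_inter}
        if any_split:
            row["dE_many_body"] = (h.emb_low / h.z_molecules
                                   - ref.emb_low / ref.z_molecules) * HARTREE_TO_KJMOL
        rows[name] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return StabilityTable(reference_polymorph=reference, frame=frame)


def stability_table_from_components(components: Mapping[str, tuple[float, float]],
                                    reference: str) -> StabilityTable:
    """Build a stability table directly from (ΔE_intra, ΔE_inter) pairs in
    kJ mol⁻¹ — the form in which published decompositions are tabulated."""
    if reference not in components:
        raise KeyError(f"reference polymorph {reference!r} not among entries")
    rows = {}
    for name, (intra, inter) in sorted(components.items()):
        rows[name] = {"dE_intra": intra, "dE_inter": inter,
                      "dE_lattice": intra + inter}
    return StabilityTable(reference_polymorph=reference,
                          frame=pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# error statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorStats:
    """rms and mean signed deviation (negative mean = overbound on average)."""

    rms: float
    mean_signed: float
    n: int


def rms_vs_reference(values: Sequence[float],
                     reference: Sequence[float]) -> ErrorStats:
    """Deviation statistics of interaction energies against a reference level.

    Sign convention: deviation = value − reference, so interaction energies
    more negative than the reference (overbinding) give a negative mean
    signed deviation.
    """
    v = np.asarray(values, dtype=float)
    r = np.asarray(reference, dtype=float)
    if v.size == 0:
        raise ValueError("empty energy list")
    if v.shape != r.shape:
        raise ValueError("value/reference length mismatch")
    diff = v - r
    return ErrorStats(rms=float(np.sqrt(np.mean(diff ** 2))),
                      mean_signed=float(np.mean(diff)), n=int(v.size))
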