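"""Harmonic vibrational thermochemistry and the two-structure temperature model.

Γ-point harmonic frequencies of the crystal cell feed the standard harmonic-
oscillator partition function to give ZPE, thermal vibrational energy,
entropy, and the Helmholtz vibrational free energy per molecule.  The Gibbs
free energy mixes a high-level electronic energy with the (cheaper) harmonic
phonon free energy,

    G(T, P) = U_el + F_vib + PV,

with the PV term negligible for a crystal at ambient pressure and defaulted
to zero.  Temperature dependence of the underlying structures is captured by
a two-structure approximation: fully relaxed cells stand in for 0 K, and
fixed-cell optimizations at the room-temperature lattice parameters stand in
for 298 K; quantities at other temperatures (e.g. a 423 K transition) come
from linear extrapolation of the two computed points.  The sign pattern of
ΔG(T) classifies a polymorph pair as enantiotropic (stability order switches
with temperature) or monotropic (one form preferred throughout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import constants as const

from .crystal_io import TAG_FIXED_CELL_RT, TAG_RELAXED_0K

logger = logging.getLogger("cspfrag")

#: hc·N_A in (kJ/mol)/cm⁻¹ — converts a wavenumber to a molar energy
WAVENUMBER_TO_KJMOL = const.h * const.c * 100.0 * const.Avogadro / 1000.0
#: gas constant in kJ/(mol·K)
R_KJMOL = const.R / 1000.0

ROOM_T = 298.15
#: default extrapolation target: the 423 K (150 °C) transition temperature
DEFAULT_T_EXT = 423.0

#: residual modes below this (cm⁻¹) after acoustic filtering draw a warning
SOFT_MODE_WARN = 5.0


@dataclass
class FrequencySet:
    """Γ-point harmonic mode list (cm⁻¹) for one crystal cell."""

    frequencies: np.ndarray
    z_molecules: int
    structure_tag: str = TAG_RELAXED_0K

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float).ravel()
        if self.z_molecules < 1:
            raise ValueError("z_molecules must be >= 1")

    def drop_acoustic(self) -> "FrequencySet":
        """Remove the three zero-frequency acoustic translations.

        The three modes of smallest magnitude are dropped; any surviving mode
        below ``SOFT_MODE_WARN`` cm⁻¹ draws a warning since near-zero optical
        modes dominate (and destabilize) the low-temperature entropy.
        """
        if len(self.frequencies) < 4:
            raise ValueError("need more than three modes to drop the acoustic set")
        order = np.argsort(np.abs(self.frequencies))
        kept = np.sort(self.frequencies[order[3:]])
        n_soft = int(np.sum(np.abs(kept) < SOFT_MODE_WARN))
        if n_soft:
            logger.warning("%d optical mode(s) below %.0f cm⁻¹ after acoustic "
                           "filtering", n_soft, SOFT_MODE_WARN)
        return FrequencySet(kept, self.z_molecules, self.structure_tag)

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "frequencies": [float(f) for f in self.frequencies],
            "z_molecules": int(self.z_molecules),
            "structure_tag": self.structure_tag,
        }, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "FrequencySet":
        data = yaml.safe_load(text)
        return cls(np.array(data["frequencies"], dtype=float),
                   int(data["z_molecules"]),
                   str(data.get("structure_tag", TAG_RELAXED_0K)))


@dataclass(frozen=True)
class ThermoRecord:
    """Harmonic thermodynamic state at one temperature, kJ mol⁻¹ per molecule.

    Satisfies f_vib = zpe + u_vib − T·s_vib identically, h = u_el + zpe +
    u_vib + pv, and g = u_el + f_vib + pv.
    """

    T: float
    u_el: float
    zpe: float
    u_vib: float
    s_vib: float        # kJ/(mol·K)
    pv: float = 0.0

    @property
    def f_vib(self) -> float:
        return self.zpe + self.u_vib - self.T * self.s_vib

    @property
    def h(self) -> float:
        return self.u_el + self.zpe + self.u_vib + self.pv

    @property
    def g(self) -> float:
        return self.u_el + self.f_vib + self.pv


def harmonic_thermo(f: FrequencySet, u_el: float, T: float,
                    pv: float = 0.0) -> ThermoRecord:
    """Harmonic-oscillator thermodynamics per molecule.

    ``u_el`` is the electronic (lattice) energy per molecule in kJ mol⁻¹ —
    typically a fragment-assembled value, so the Gibbs energy mixes a
    high-level electronic energy with lower-level phonons.  Per-mode sums are
    normalized by ``z_molecules``.  Imaginary modes (entered as negative
    frequencies) mean the structure is not a minimum and raise an error.
    """
    if T < 0:
        raise ValueError("temperature must be non-negative")
    nu = f.frequencies
    if np.any(nu <= 0):
        raise ValueError("negative/imaginary frequency present: structure not a minimum")
    e_modes = nu * WAVENUMBER_TO_KJMOL       # hc·ν̃·N_A per mode, kJ/mol
    zpe = float(0.5 * e_modes.sum())
    if T == 0.0:
        u_vib = s_vib = 0.0
    else:
        x = np.minimum(e_modes / (R_KJMOL * T), 700.0)
        expm = np.expm1(x)
        u_vib = float(np.sum(e_modes / expm))
        # ln(1 - e^-x) without cancellation: ln(expm1(x)) - x for small x,
        # log1p(-e^-x) for large x
        log_term = np.where(x < 1.0,
                            np.log(expm) - x,
                            np.log1p(-np.exp(-x)))
        s_vib = float(R_KJMOL * np.sum(x / expm - log_term))
    z = f.z_molecules
    return ThermoRecord(T=T, u_el=u_el, zpe=zpe / z, u_vib=u_vib / z,
                        s_vib=s_vib / z, pv=pv)


def delta_thermo(a: ThermoRecord, b: ThermoRecord) -> dict[str, float]:
    """Relative thermodynamics b − a at a common temperature.

    Note ΔH at 0 K reduces to ΔE_lattice + ΔZPE: a lattice-energy gap of
    5.8 kJ mol⁻¹ with a −1.2 kJ mol⁻¹ relative ZPE gives ΔH(0 K) = 4.6.
    """
    if abs(a.T - b.T) > 1e-9:
        raise ValueError(f"mismatched temperatures: {a.T} vs {b.T}")
    return {
        "T": a.T,
        "dU_el": b.u_el - a.u_el,
        "dZPE": b.zpe - a.zpe,
        "dU_vib": b.u_vib - a.u_vib,
        "dS_vib": b.s_vib - a.s_vib,
        "dF_vib": b.f_vib - a.f_vib,
        "dH": b.h - a.h,
        "dG": b.g - a.g,
    }


def linear_extrapolate(point1: tuple[float, float], point2: tuple[float, float],
                       t_target: float) -> float:
    """Value on the straight line through two (T, value) points at t_target.

    This is the two-structure temperature model's reach beyond its computed
    endpoints, e.g. taking ΔH(0 K) and ΔH(298 K) to the 423 K transition.
    Exact at the endpoints.
    """
    t1, v1 = point1
    t2, v2 = point2
    if t1 == t2:
        raise ValueError("temperatures of the two points must differ")
    return v1 + (v2 - v1) * (t_target - t1) / (t2 - t1)


# ---------------------------------------------------------------------------
# stability vs temperature
# ---------------------------------------------------------------------------

@dataclass
class PairStability:
    """ΔH/ΔG lines of one polymorph against the reference form."""

    polymorph: str
    dH_0K: float
    dG_0K: float
    dH_RT: float
    dG_RT: float
    extrapolated: dict[float, dict[str, float]] = field(default_factory=dict)
    classification: str = "monotropic"
    crossing_T: float | None = None


@dataclass
class StabilityProfile:
    reference: str
    t_max: float
    pairs: dict[str, PairStability]

    def frame(self):
        import pandas as pd
        rows = {}
        for name, p in sorted(self.pairs.items()):
            row = {"dH_0K": p.dH_0K, "dG_0K": p.dG_0K,
                   "dH_298K": p.dH_RT, "dG_298K": p.dG_RT}
            for t, vals in sorted(p.extrapolated.items()):
                row[f"dH_{t:g}K"] = vals["dH"]
                row[f"dG_{t:g}K"] = vals["dG"]
            row["classification"] = p.classification
            row["crossing_T"] = p.crossing_T
            rows[name] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def _zero_crossing(t1: float, v1: float, t2: float, v2: float,
                   t_max: float) -> float | None:
    if v1 == v2:
        return None
    tc = t1 - v1 * (t2 - t1) / (v2 - v1)
    if 0.0 < tc <= t_max and abs(v1) > 0:
        return tc
    return None


def stability_vs_temperature(records: Mapping[str, Mapping[str, ThermoRecord]],
                             reference: str,
                             t_grid: Sequence[float] = (DEFAULT_T_EXT,),
                             t_max: float | None = None) -> StabilityProfile:
    """Temperature profile of relative stabilities under the two-structure model.

    ``records[name]`` maps structure tags to ThermoRecords: the relaxed-cell
    record must be evaluated at 0 K and the fixed-cell room-temperature record
    at 298.15 K.  ΔH(T) and ΔG(T) lines are drawn through the two computed
    points for each polymorph versus the reference; a pair is classified
    enantiotropic iff its ΔG line crosses zero strictly inside (0, t_max]
    (stability order switches with temperature), else monotropic.  Swapping
    the reference flips every sign but leaves crossings — and hence the
    classification — unchanged.
    """
    if reference not in records:
        raise KeyError(f"reference polymorph {reference!r} missing")
    for name, tags in records.items():
        for tag in (TAG_RELAXED_0K, TAG_FIXED_CELL_RT):
            if tag not in tags:
                raise KeyError(f"polymorph {name!r} lacks the {tag!r} record")
    tm = t_max if t_max is not None else max([*t_grid, ROOM_T])
    ref0 = records[reference][TAG_RELAXED_0K]
    refrt = records[reference][TAG_FIXED_CELL_RT]

    pairs: dict[str, PairStability] = {}
    for name, tags in records.items():
        if name == reference:
            continue
        d0 = delta_thermo(ref0, tags[TAG_RELAXED_0K])
        drt = delta_thermo(refrt, tags[TAG_FIXED_CELL_RT])
        p = PairStability(polymorph=name,
                          dH_0K=d0["dH"], dG_0K=d0["dG"],
                          dH_RT=drt["dH"], dG_RT=drt["dG"])
        for t in t_grid:
            p.extrapolated[float(t)] = {
                "dH": linear_extrapolate((0.0, p.dH_0K), (ROOM_T, p.dH_RT), t),
                "dG": linear_extrapolate((0.0, p.dG_0K), (ROOM_T, p.dG_RT), t),
            }
        tc = _zero_crossing(0.0, p.dG_0K, ROOM_T, p.dG_RT, tm)
        if tc is not None:
            p.classification = "enantiotropic"
            p.crossing_T = tc
        pairs[name] = p
    return StabilityProfile(reference=reference, t_max=tm, pairs=pairs)
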