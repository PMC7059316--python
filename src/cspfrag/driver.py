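"""End-to-end polymorph ranking workflow.

Reads a structured configuration naming the polymorphs, their structure files
per condition (relaxed 0 K cell / fixed room-temperature cell), frequency
lists, and per-polymorph energy ledgers; runs fragment enumeration → hybrid
assembly → stability decomposition → harmonic thermochemistry → temperature
profile; and writes CSV reports.  Deterministic: identical inputs give
byte-identical outputs.  Every default actually used (cutoff, levels,
temperatures) is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from .crystal_io import (HARTREE_TO_KJMOL, TAG_FIXED_CELL_RT, TAG_RELAXED_0K,
                         parse_cif, perceive_molecules)
from .energetics import StabilityTable, decompose_stabilities
from .fragmentation import (DEFAULT_SR_CUTOFF, EnergyLedger, HMBIEnergy,
                            assemble_hmbi, enumerate_fragments)
from .thermochem import (DEFAULT_T_EXT, ROOM_T, FrequencySet, StabilityProfile,
                         harmonic_thermo, stability_vs_temperature)

logger = logging.getLogger("cspfrag")


class ConfigError(ValueError):
    """Raised when a ranking configuration fails validation."""


@dataclass
class PolymorphEntry:
    name: str
    structures: dict[str, Path]      # tag -> CIF path
    frequencies: dict[str, Path]     # tag -> frequency YAML path
    ledger: Path

    def validate(self) -> None:
        if not self.structures:
            raise ConfigError(f"polymorph {self.name!r} lists no structures")
        for p in [*self.structures.values(), *self.frequencies.values(), self.ledger]:
            if not Path(p).exists():
                raise ConfigError(f"polymorph {self.name!r}: missing file {p}")


@dataclass
class RankingConfig:
    polymorphs: list[PolymorphEntry]
    reference: str
    high_level: str
    low_level: str
    cutoff: float = DEFAULT_SR_CUTOFF
    temperatures: list[float] = field(default_factory=lambda: [DEFAULT_T_EXT])
    output_dir: Path = Path("cspfrag-out")

    def validate(self) -> None:
        names = [p.name for p in self.polymorphs]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate polymorph names")
        if self.reference not in names:
            raise ConfigError(f"reference polymorph {self.reference!r} not configured")
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be positive")
        for p in self.polymorphs:
            p.validate()

    @classmethod
    def from_yaml(cls, text: str, base_dir: Path | str = ".") -> "RankingConfig":
        base = Path(base_dir)
        data = yaml.safe_load(text)
        try:
            entries = []
            for item in data["polymorphs"]:
                entries.append(PolymorphEntry(
                    name=str(item["name"]),
                    structures={t: base / p for t, p in item.get("structures", {}).items()},
                    frequencies={t: base / p for t, p in item.get("frequencies", {}).items()},
                    ledger=base / item["ledger"],
                ))
            levels = data.get("levels", {})
            return cls(
                polymorphs=entries,
                reference=str(data["reference"]),
                high_level=str(levels.get("high", "MP2D")),
                low_level=str(levels.get("low", "HF")),
                cutoff=float(data.get("cutoff", DEFAULT_SR_CUTOFF)),
                temperatures=[float(t) for t in data.get("temperatures", [DEFAULT_T_EXT])],
                output_dir=base / data.get("output", "cspfrag-out"),
            )
        except KeyError as exc:
            raise ConfigError(f"missing configuration key: {exc}") from exc

    @classmethod
    def load(cls, path: Path | str) -> "RankingConfig":
        path = Path(path)
        return cls.from_yaml(path.read_text(), base_dir=path.parent)


@dataclass
class RankingResult:
    decomposition: dict[str, StabilityTable]   # per structure tag
    profile: StabilityProfile | None
    hmbi: dict[str, dict[str, HMBIEnergy]]     # name -> tag -> energy


class StageError(RuntimeError):
    """An error in one pipeline stage, annotated with polymorph and stage."""


def _stage(polymorph: str, stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"[{polymorph} / {stage}] {exc}") from exc


def run_ranking(config: RankingConfig, write_reports: bool = True) -> RankingResult:
    """Execute the ranking pipeline described by ``config``.

    For each polymorph and structure condition: parse the CIF, perceive
    molecules, enumerate fragments at the configured cutoff, and assemble the
    hybrid energy from the polymorph's ledger.  Relative lattice-energy
    decompositions are produced per condition; when frequency sets are
    available for both conditions, harmonic enthalpies and Gibbs energies at
    0 K and 298.15 K and the linear temperature profile (with the
    enantiotropic/monotropic classification) follow.  Reports are written
    only after the whole pipeline succeeds.
    """
    config.validate()
    logger.info("ranking %d polymorphs; reference=%s high=%s low=%s cutoff=%.2f Å "
                "temperatures=%s", len(config.polymorphs), config.reference,
                config.high_level, config.low_level, config.cutoff,
                config.temperatures)

    hmbi: dict[str, dict[str, HMBIEnergy]] = {}
    thermo: dict[str, dict[str, object]] = {}
    for entry in config.polymorphs:
        ledger = _stage(entry.name, "ledger",
                        lambda: EnergyLedger.from_yaml(Path(entry.ledger).read_text()))
        hmbi[entry.name] = {}
        thermo[entry.name] = {}
        for tag, cif_path in sorted(entry.structures.items()):
            s = _stage(entry.name, f"parse:{tag}",
                       parse_cif, Path(cif_path).read_text(), tag)
            _stage(entry.name, f"perceive:{tag}", perceive_molecules, s)
            jobs = _stage(entry.name, f"fragment:{tag}",
                          enumerate_fragments, s, config.cutoff)
            h = _stage(entry.name, f"assemble:{tag}", assemble_hmbi,
                       jobs, ledger, config.high_level, config.low_level)
            hmbi[entry.name][tag] = h
            if tag in entry.frequencies:
                freqs = _stage(entry.name, f"frequencies:{tag}",
                               lambda p=entry.frequencies[tag]:
                               FrequencySet.from_yaml(Path(p).read_text()))
                T = 0.0 if tag == TAG_RELAXED_0K else ROOM_T
                u_el = h.per_molecule * HARTREE_TO_KJMOL
                thermo[entry.name][tag] = _stage(
                    entry.name, f"thermo:{tag}", harmonic_thermo, freqs, u_el, T)

    decomposition = {}
    for tag in sorted({t for by_tag in hmbi.values() for t in by_tag}):
        entries = {n: by_tag[tag] for n, by_tag in hmbi.items() if tag in by_tag}
        if config.reference in entries and len(entries) > 1:
            decomposition[tag] = decompose_stabilities(entries, config.reference)

    profile = None
    complete = {n: t for n, t in thermo.items()
                if TAG_RELAXED_0K in t and TAG_FIXED_CELL_RT in t}
    if config.reference in complete and len(complete) > 1:
        profile = stability_vs_temperature(complete, config.reference,
                                           t_grid=config.temperatures)

    result = RankingResult(decomposition=decomposition, profile=profile, hmbi=hmbi)
    if write_reports:
        _write_reports(config, result)
    return result


def _write_reports(config: RankingConfig, result: RankingResult) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tag, table in result.decomposition.items():
        (out / f"decomposition_{tag}.csv").write_text(table.to_csv())
    if result.profile is not None:
        (out / "profile.csv").write_text(
            result.profile.frame().to_csv(index_label="polymorph"))
        # stability.csv mirrors the published table layout
        rows = []
        for name, p in sorted(result.profile.pairs.items()):
            t_ext = config.temperatures[0] if config.temperatures else DEFAULT_T_EXT
            ext = p.extrapolated.get(float(t_ext), {})
            dec0 = result.decomposition.get(TAG_RELAXED_0K)
            intra = inter = lat = ""
            if dec0 is not None and name in dec0.frame.index:
                r = dec0.row(name)
                intra, inter, lat = (f"{r['dE_intra']:.6f}", f"{r['dE_inter']:.6f}",
                                     f"{r['dE_lattice']:.6f}")
            rows.append(",".join([
                name, intra, inter, lat, f"{p.dH_0K:.6f}", f"{p.dH_RT:.6f}",
                f"{ext.get('dH', float('nan')):.6f}", f"{p.dG_RT:.6f}",
                p.classification]))
        header = ("polymorph,dE_intra,dE_inter,dE_lattice,dH_0K,dH_298K,"
                  "dH_ext,dG_298K,classification")
        (out / "stability.csv").write_text("\n".join([header, *rows]) + "\n")
    logger.info("reports written to %s", out)
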