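"""Experiment harness: peptide registry, the four-condition design,
replicate management, report tables, and deterministic test fixtures.

The registry holds the five alpha-helical study peptides (two designed,
three fragments of natural proteins).  Each peptide is simulated under
four conditions -- unassisted ("free"), end-restrained without torque
("restrained"), and end-restrained with clockwise ("cw") or
counterclockwise ("ccw") enforced rotation -- with a configurable number
of replicates per cell, three by default (12 runs per peptide).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analysis import FoldingResult, folding_time, rmsd_series, summarize_runs
from .chain import (Conformation, Sequence, add_handles, build_extended_conformation,
                    build_ideal_helix, build_topology)
from .config import Config, save_config
from .dynamics import SimulationError, SimulationSettings, run_simulation
from .io import write_driver_log, write_pdb, write_rmsd_log, write_xyz
from .machine import MachineProtocol

__all__ = ["PeptideRegistryEntry", "ConditionSpec", "RunPlan", "CONDITIONS",
           "load_registry", "make_condition", "derive_seed", "run_single",
           "run_plan", "table2_report", "generate_fixtures"]

CONDITIONS = ("free", "restrained", "cw", "ccw")

# Human-readable condition labels in the published column order.
CONDITION_LABELS = {
    "free": "No rotation, no restraints",
    "restrained": "No rotation, restrained ends",
    "cw": "Restrained ends, rotation clockwise",
    "ccw": "Restrained ends, rotation counterclockwise",
}


@dataclass(frozen=True)
class PeptideRegistryEntry:
    id: str
    description: str
    notation: str          # core sequence, repeat notation allowed
    pdb_id: str | None     # experimental reference, informational
    native: str = "ideal-helix"

    @property
    def core(self) -> str:
        from .chain import expand_sequence_notation

        return expand_sequence_notation(self.notation)


_REGISTRY = (
    PeptideRegistryEntry(
        "P1", "Peptide Fs (Folded short), designed de novo",
        "AAAA(AAARA)3", None),
    PeptideRegistryEntry(
        "P2", "First helix of the three-helix bundle, designed de novo",
        "SWAEFKQRLAAIKTR", "2A3D"),
    PeptideRegistryEntry(
        "P3", "Fragment of the tetramerization domain of potassium channel Kv7.1",
        "HLNLMVRIKELQRRLDQSL", "6UZZ"),
    PeptideRegistryEntry(
        "P4", "Loop and third helix of the villin headpiece fragment HP35",
        "PLWLQQHLLKEKGLF", "2F4K"),
    PeptideRegistryEntry(
        "P5", "Fragment of the coiled-coil region of pyrin",
        "KIQKQLEHLKKLRKSGEEQRS", "4CD4"),
)


def load_registry() -> dict[str, PeptideRegistryEntry]:
    """The five built-in study peptides, keyed P1-P5."""
    return {e.id: e for e in _REGISTRY}


@dataclass(frozen=True)
class ConditionSpec:
    """One of the four experiment conditions.

    ``sign`` is relative to the clockwise convention: +1 for cw, -1 for
    ccw, 0 when rotation is off.
    """

    name: str
    rotate: bool
    restrain: bool
    sign: int

    def protocol(self, config: Config, top, start: Conformation) -> MachineProtocol:
        return MachineProtocol.for_condition(self.name, config.machine, top, start)


def make_condition(name: str) -> ConditionSpec:
    table = {
        "free": ConditionSpec("free", False, False, 0),
        "restrained": ConditionSpec("restrained", False, True, 0),
        "cw": ConditionSpec("cw", True, True, +1),
        "ccw": ConditionSpec("ccw", True, True, -1),
    }
    try:
        return table[name]
    except KeyError:
        raise ValueError(f"unknown condition {name!r}") from None


def derive_seed(base_seed: int, peptide: str, condition: str, replicate: int) -> int:
    """Deterministic per-run seed; replicates never share seeds."""
    key = f"{base_seed}|{peptide}|{condition}|{replicate}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


@dataclass
class RunPlan:
    """The full design matrix: peptides x conditions x replicates."""

    peptides: tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5")
    conditions: tuple[str, ...] = CONDITIONS
    replicates: int = 3
    base_seed: int = 2021
    durations_ps: dict = field(default_factory=dict)  # condition -> ps

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def duration(self, config: Config, condition: str) -> float:
        if condition in self.durations_ps:
            return float(self.durations_ps[condition])
        p = config.plan
        return {"free": p.duration_free_ps, "restrained": p.duration_restrained_ps,
                "cw": p.duration_cw_ps, "ccw": p.duration_ccw_ps}[condition]

    def cells(self):
        for pid in self.peptides:
            for cond in self.conditions:
                for rep in range(self.replicates):
                    yield pid, cond, rep


def _prepare_system(entry: PeptideRegistryEntry):
    seq = add_handles(Sequence(entry.core), 2)
    top = build_topology(seq)
    start = build_extended_conformation(top)
    native_conf, sel = build_ideal_helix(top, core_only=True)
    native = native_conf.positions[sel]
    return top, start, native, sel


def run_single(entry: PeptideRegistryEntry, condition: str, duration_ps: float,
               seed: int, config: Config, out_dir: Path | None = None,
               save_traj: bool = True):
    """Run one simulation cell and return (FoldingResult, Trajectory, RmsdSeries)."""
    top, start, native, sel = _prepare_system(entry)
    proto = MachineProtocol.for_condition(condition, config.machine, top, start)
    settings = SimulationSettings.from_params(config.integrator, duration_ps, seed)
    traj = run_simulation(top, start, config.forcefield, proto, settings)
    series = rmsd_series(traj, native, sel)
    t_fold = folding_time(series, config.analysis.rmsd_threshold_nm)
    result = FoldingResult(entry.id, condition, seed, t_fold, duration_ps,
                           float(series.values[-1]))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_rmsd_log(out_dir / "rmsd.tsv", series.times, series.values)
        write_driver_log(out_dir / "driver.tsv", traj)
        if save_traj:
            write_xyz(out_dir / "traj.xyz", top, traj)
        with open(out_dir / "result.json", "w") as fh:
            json.dump(dataclasses.asdict(result), fh, indent=1)
    return result, traj, series


def run_plan(plan: RunPlan, config: Config, out_dir: str | Path) -> list[FoldingResult]:
    """Execute the design matrix with derived seeds; resumable via manifest.

    Completed cells recorded in ``manifest.json`` are skipped on rerun; a
    run that aborts is recorded as failed and the remaining runs proceed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "config.yaml")
    manifest_path = out_dir / "manifest.json"
    manifest: dict[str, dict] = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)

    registry = load_registry()
    results: list[FoldingResult] = []
    for pid, cond, rep in plan.cells():
        key = f"{pid}/{cond}/rep{rep}"
        cell_dir = out_dir / pid / cond / f"rep{rep}"
        entry_m = manifest.get(key)
        if entry_m and entry_m.get("status") == "done":
            with open(cell_dir / "result.json") as fh:
                d = json.load(fh)
            results.append(FoldingResult(**d))
            continue
        seed = derive_seed(plan.base_seed, pid, cond, rep)
        duration = plan.duration(config, cond)
        try:
            result, _, _ = run_single(registry[pid], cond, duration, seed,
                                      config, cell_dir,
                                      save_traj=config.plan.save_trajectories)
        except SimulationError as err:
            manifest[key] = {"status": "failed", "seed": seed, "error": str(err)}
        else:
            results.append(result)
            manifest[key] = {"status": "done", "seed": seed}
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1)
    return results


def table2_report(results: list[FoldingResult], path: str | Path | None = None,
                  durations_note: bool = True):
    """Folding-rate summary table in the published layout.

    One row per peptide and one column per condition in the order free,
    restrained, cw, ccw; each cell lists the replicate ``t/duration``
    strings, with equal numbers meaning folding was not observed.  Written
    as TSV (and CSV alongside) when ``path`` is given.
    """
    if not results:
        raise ValueError("no results to report")
    df = summarize_runs(results)
    if path is not None:
        path = Path(path)
        df.to_csv(path, sep="\t")
        df.to_csv(path.with_suffix(".csv"))
    return df


def generate_fixtures(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Deterministic fixture files for tests; no downloads, same seed same bytes.

    Kinds: ``extended``, ``helix``, ``perturbed-helix``, ``synthetic-pdb``
    (a small helical fragment constructed by this package, not an
    experimental structure), and ``rmsd-series`` (a series crossing 0.2 nm
    at a known index).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entry = load_registry()["P2"]
    top, start, _, _ = _prepare_system(entry)
    written: list[Path] = []

    if kind == "extended":
        p = out_dir / "extended.pdb"
        write_pdb(p, top, start)
        written.append(p)
    elif kind == "helix":
        p = out_dir / "helix.pdb"
        write_pdb(p, top, build_ideal_helix(top))
        written.append(p)
    elif kind == "perturbed-helix":
        rng = np.random.default_rng(seed)
        conf = build_ideal_helix(top)
        conf.positions += 0.01 * rng.standard_normal(conf.positions.shape)
        p = out_dir / "perturbed_helix.pdb"
        write_pdb(p, top, conf)
        written.append(p)
    elif kind == "synthetic-pdb":
        core_top = build_topology(Sequence(entry.core))
        conf = build_ideal_helix(core_top)
        p = out_dir / "synthetic_helix_fragment.pdb"
        write_pdb(p, core_top, conf)
        written.append(p)
    elif kind == "rmsd-series":
        times = np.arange(0.0, 50.0, 1.0)
        vals = np.maximum(0.05, 0.5 - 0.02 * times)  # crosses 0.2 nm at t = 15
        p = out_dir / "rmsd_series.tsv"
        write_rmsd_log(p, times, vals)
        written.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
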