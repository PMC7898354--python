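"""Shared fixtures: the alanine-rich study peptide and the four-condition
simulation batch reused by the folding-asymmetry and chain-winding tests."""

from __future__ import annotations

import numpy as np
import pytest

from torquefold.analysis import (folding_time, helicity, rmsd_series,
                                 rotation_propagation)
from torquefold.chain import (Sequence, add_handles, build_extended_conformation,
                              build_ideal_helix, build_topology)
from torquefold.config import Config
from torquefold.dynamics import SimulationSettings, run_simulation
from torquefold.machine import MachineProtocol

P1_CORE = "AAAAAAARAAAARAAAARA"  # Fs peptide, 19 residues


@pytest.fixture(scope="session")
def p1_system():
    """Topology, extended start, and native helix reference for the Fs peptide."""
    seq = add_handles(Sequence(P1_CORE), 2)
    top = build_topology(seq)
    ext = build_extended_conformation(top)
    hel, sel = build_ideal_helix(top, core_only=True)
    return top, ext, hel.positions[sel], sel


@pytest.fixture(scope="session")
def default_config():
    return Config()


@pytest.fixture()
def random_conformations(p1_system):
    """Factory for mildly perturbed extended conformations (finite energies)."""
    top, ext, _, _ = p1_system

    def make(n, scale=0.03, seed=1234):
        rng = np.random.default_rng(seed)
        return [ext.positions + scale * rng.standard_normal(ext.positions.shape)
                for _ in range(n)]

    return make


# Budgets for the four-condition asymmetry batch: the driven conditions get
# the short budget, the two control conditions four times as long.
DRIVEN_BUDGET_PS = 800.0
CONTROL_BUDGET_PS = 4 * DRIVEN_BUDGET_PS
BATCH_SEEDS = (101, 102, 103, 104, 105)


@pytest.fixture(scope="session")
def asymmetry_batch(p1_system, default_config):
    """Five replicates of all four conditions on the Fs peptide.

    Returns ``{condition: [run record, ...]}`` where each record carries the
    first-passage folding time, the final RMSD, and the terminal-residue
    winding series.  This is the single expensive fixture of the suite and
    backs both the directional-asymmetry and the chain-winding tests.
    """
    top, ext, native, sel = p1_system
    cfg = default_config
    out: dict[str, list[dict]] = {}
    for cond in ("cw", "ccw", "free", "restrained"):
        dur = DRIVEN_BUDGET_PS if cond in ("cw", "ccw") else CONTROL_BUDGET_PS
        runs = []
        for seed in BATCH_SEEDS:
            proto = MachineProtocol.for_condition(cond, cfg.machine, top, ext)
            st = SimulationSettings.from_params(cfg.integrator, dur, seed)
            traj = run_simulation(top, ext, cfg.forcefield, proto, st)
            series = rmsd_series(traj, native, sel)
            wind = rotation_propagation(traj, top)
            runs.append({
                "seed": seed,
                "duration": dur,
                "fold_time": folding_time(series, cfg.analysis.rmsd_threshold_nm),
                "final_rmsd": float(series.values[-1]),
                "final_helicity": helicity(traj.frame(-1), top),
                "times": traj.times,
                # winding of the last core (non-handle) residue
                "terminal_winding": wind[:, -3],
                "driven_winding": wind[:, -1],
            })
        out[cond] = runs
    return out
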