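"""Langevin (BAOAB) dynamics with an energy ledger.

Implicit solvent replaces explicit water: friction and noise thermalise
the peptide at the target temperature while the machine potential, when
enabled, injects work through its explicit time dependence.  One random
stream per run, seeded once, with draws in a fixed order, makes every
trajectory bitwise reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .chain import Conformation, Topology
from .config import KB, ForceFieldParams, IntegratorParams
from .energy import CompiledForceField
from .machine import MachineProtocol

__all__ = ["SimulationSettings", "SimulationState", "Trajectory",
           "SimulationError", "init_state", "langevin_step",
           "run_simulation", "kinetic_temperature"]


class SimulationError(RuntimeError):
    """Raised when the integration produces non-finite forces or energies.

    Carries the partial trajectory accumulated so far in ``trajectory``.
    """

    def __init__(self, message: str, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class SimulationSettings:
    """Integration settings for one run."""

    temperature: float = 300.0    # K
    dt: float = 0.002             # ps
    gamma: float = 1.0            # ps^-1
    duration_ps: float = 100.0
    report_interval_ps: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0 or self.gamma < 0:
            raise ValueError("temperature and gamma must be >= 0")
        if self.duration_ps < self.dt:
            raise ValueError("duration must cover at least one step")

    @classmethod
    def from_params(cls, params: IntegratorParams, duration_ps: float,
                    seed: int) -> "SimulationSettings":
        return cls(temperature=params.temperature, dt=params.dt,
                   gamma=params.gamma, duration_ps=duration_ps,
                   report_interval_ps=params.report_interval_ps, seed=seed)


@dataclass
class SimulationState:
    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    time: float
    rng: np.random.Generator
    forces: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.masses[:, None] * self.velocities**2))


@dataclass
class Trajectory:
    """Frames plus per-frame scalar channels (energies, torque, work, T)."""

    times: np.ndarray
    positions: np.ndarray            # (n_frames, n_atoms, 3)
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        for name, ch in self.channels.items():
            if len(ch) != len(self.times):
                raise ValueError(f"channel {name!r} length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> Conformation:
        return Conformation(self.positions[i].copy(), time=float(self.times[i]))


def init_state(conf: Conformation, top: Topology,
               settings: SimulationSettings) -> SimulationState:
    """Maxwell-Boltzmann velocities at T from the seed, COM motion removed."""
    rng = np.random.default_rng(settings.seed)
    m = top.masses
    if settings.temperature > 0:
        sigma = np.sqrt(KB * settings.temperature / m)
        v = rng.standard_normal((top.n_atoms, 3)) * sigma[:, None]
        v -= np.sum(m[:, None] * v, axis=0) / np.sum(m)
    else:
        v = np.zeros((top.n_atoms, 3))
    return SimulationState(positions=conf.positions.copy(), velocities=v,
                           masses=m.copy(), time=conf.time, rng=rng)


def kinetic_temperature(state: SimulationState) -> float:
    """Instantaneous kinetic temperature 2 E_kin / (3 N k_B) in kelvin."""
    n = state.n_atoms
    if n < 1:
        raise ValueError("state has no atoms")
    return 2.0 * state.kinetic_energy() / (3.0 * n * KB)


def langevin_step(state: SimulationState,
                  force_eval: Callable[[np.ndarray, float], np.ndarray],
                  settings: SimulationSettings) -> SimulationState:
    """One BAOAB step: B (half kick), A (half drift), O, A, B.

    ``force_eval(positions, time)`` returns forces in kJ/mol/nm.  The force
    at the end of the step is cached on the state and reused as the first
    half-kick of the next step, so each step costs one force evaluation.
    Mutates and returns ``state``.
    """
    dt = settings.dt
    m = state.masses[:, None]
    if state.forces is None:
        state.forces = force_eval(state.positions, state.time)
    half = 0.5 * dt
    v = state.velocities
    x = state.positions
    v += half * state.forces / m
    x += half * v
    c1 = np.exp(-settings.gamma * dt)
    if settings.gamma > 0 and settings.temperature > 0:
        c2 = np.sqrt(KB * settings.temperature / m * (1.0 - c1 * c1))
        v *= c1
        v += c2 * state.rng.standard_normal(x.shape)
    else:
        v *= c1
    x += half * v
    state.time += dt
    f = force_eval(x, state.time)
    if not np.all(np.isfinite(f)):
        bad = int(np.argwhere(~np.isfinite(f))[0][0])
        raise SimulationError(
            f"non-finite force on atom {bad} at t = {state.time:.3f} ps")
    v += half * f / m
    state.forces = f
    return state


NLIST_SKIN = 0.25  # nm; Verlet-list skin for the repulsion pair list


def run_simulation(top: Topology, start: Conformation,
                   ff_params: ForceFieldParams, protocol: MachineProtocol,
                   settings: SimulationSettings) -> Trajectory:
    """Integrate the full model and record frames plus scalar channels.

    Total force at every step is the force-field force plus the machine
    force evaluated at the current reference angle.  Driver work is
    accumulated every step as torque * s * omega * dt.  Identical inputs
    and seed give identical output.

    The inner loop runs in a compiled kernel, one chunk per reporting
    interval, implementing exactly the BAOAB scheme of
    :func:`langevin_step`; noise is drawn from the state's generator in
    the same fixed order.
    """
    from . import _kernels as K

    cff = CompiledForceField(top, ff_params)
    state = init_state(start, top, settings)
    omega_signed = protocol.direction * np.deg2rad(protocol.rate_deg_ps)
    p = ff_params

    n = top.n_atoms
    c1 = float(np.exp(-settings.gamma * settings.dt))
    if settings.gamma > 0 and settings.temperature > 0:
        c2 = np.sqrt(KB * settings.temperature / top.masses * (1.0 - c1 * c1))
        noisy = True
    else:
        c2 = np.zeros(n)
        noisy = False

    nb_idx = np.empty(cff.rep_pairs.shape[0], dtype=np.int64)
    nb_state = np.empty(1, dtype=np.int64)
    ref_pos = np.empty((n, 3))
    nb_state[0] = K.nlist_build(state.positions, cff.rep_pairs, cff.rep_cutoff,
                                NLIST_SKIN, nb_idx, ref_pos)
    eterms = np.zeros(8)
    forces = np.zeros((n, 3))

    mach = protocol
    ff_args = (cff.bonds, cff.bond_b0, p.k_bond, cff.angles, cff.angle_theta0,
               p.k_angle, cff.omega_quads, p.k_omega, cff.phi_quads,
               cff.psi_quads, cff.weights, p.eps_helix, cff.phi0, cff.psi0,
               cff.sigma_basin, p.trans_bias, p.torsion_barrier3,
               cff.hbond_pairs, p.eps_hb, p.hb_d0, p.hb_sigma,
               cff.rep_pairs, cff.rep_sigma, cff.rep_cutoff, p.eps_rep)
    mach_args = (mach.rotate, mach.k_rot, mach.group, mach.ref_rel,
                 mach.plane_idx, mach.plane_anchor, mach.k_plane,
                 mach.x_idx, mach.x_anchor, mach.k_x,
                 mach.fix_idx, mach.fix_anchor, mach.k_fix)

    K.forces_full(state.positions, state.time, forces, eterms, *ff_args,
                  nb_idx, nb_state[0], mach.rotate,
                  protocol.theta(state.time), mach.k_rot, mach.group,
                  mach.ref_rel, mach.plane_idx, mach.plane_anchor, mach.k_plane,
                  mach.x_idx, mach.x_anchor, mach.k_x, mach.fix_idx,
                  mach.fix_anchor, mach.k_fix)
    state.forces = forces

    n_steps = int(round(settings.duration_ps / settings.dt))
    stride = max(1, int(round(settings.report_interval_ps / settings.dt)))

    times: list[float] = []
    frames: list[np.ndarray] = []
    chan: dict[str, list[float]] = {k: [] for k in (
        "e_bond", "e_angle", "e_omega", "e_torsion", "e_hbond", "e_repulsion",
        "e_machine", "e_pot", "e_kin", "temperature", "theta_deg", "torque",
        "work")}
    work = 0.0

    def record() -> None:
        times.append(state.time)
        frames.append(state.positions.copy())
        for i, key in enumerate(("e_bond", "e_angle", "e_omega", "e_torsion",
                                 "e_hbond", "e_repulsion", "e_machine")):
            chan[key].append(float(eterms[i]))
        chan["e_pot"].append(float(eterms[:7].sum()))
        chan["e_kin"].append(state.kinetic_energy())
        chan["temperature"].append(kinetic_temperature(state))
        chan["theta_deg"].append(np.rad2deg(protocol.theta(state.time))
                                 if protocol.rotate else 0.0)
        chan["torque"].append(float(eterms[7]))
        chan["work"].append(work)

    record()

    def partial() -> Trajectory:
        return Trajectory(np.array(times), np.array(frames),
                          {k: np.array(v) for k, v in chan.items()})

    done = 0
    while done < n_steps:
        todo = min(stride, n_steps - done)
        if noisy:
            noise = state.rng.standard_normal((todo, n, 3))
        else:
            noise = np.zeros((todo, n, 3))
        t_new, work, bad = K.advance_chunk(
            state.positions, state.velocities, forces, state.masses,
            settings.dt, c1, c2, noise, state.time, omega_signed, work,
            *ff_args, nb_idx, nb_state, ref_pos, NLIST_SKIN,
            *mach_args, eterms)
        state.time = t_new
        done += todo
        if bad >= 0:
            raise SimulationError(
                f"non-finite force on atom {bad} at t = {state.time:.3f} ps",
                trajectory=partial())
        if not np.all(np.isfinite(eterms)):
            raise SimulationError(
                f"non-finite energy at t = {state.time:.3f} ps",
                trajectory=partial())
        record()

    return partial()
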