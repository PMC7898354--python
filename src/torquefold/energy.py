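"""Coarse-grained potential energy terms with analytic forces.

The potential is an implicit-solvent surrogate for an atomistic force
field, built from five terms:

* harmonic bonds and angles plus omega-planarity (``bonded``),
* a Gaussian helix basin on each residue's (phi, psi) pair centred at
  (-57, -47) degrees, scaled by a per-residue helix-propensity weight,
  together with a weak cosine trans bias (``torsion``),
* a Gaussian i -> i+4 O...N hydrogen-bond attraction (``hbond``),
* truncated-and-shifted r^-12 excluded-volume repulsion between all atom
  pairs more than two bonds apart (``repulsion``).

Each public routine returns ``(energy, forces)`` where forces are the
exact negative gradient of the energy; the test suite verifies every term
against a central-difference numerical oracle.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from . import _kernels as K
from .chain import Conformation, Topology
from .config import ForceFieldParams

__all__ = [
    "bonded_energy_forces",
    "torsion_energy_forces",
    "hbond_energy_forces",
    "repulsion_energy_forces",
    "total_energy_forces",
    "numerical_gradient",
    "CompiledForceField",
]

class CompiledForceField:
    """Topology + parameters flattened into kernel-ready arrays.

    Building the pair lists is O(N^2) and done once; the per-step force
    evaluation then runs entirely inside compiled kernels.
    """

    def __init__(self, top: Topology, params: ForceFieldParams):
        self.top = top
        self.params = params
        self.bonds = top.bonds
        self.bond_b0 = top.bond_b0
        self.angles = top.angles
        self.angle_theta0 = top.angle_theta0
        self.omega_quads = top.omega_quads
        self.phi_quads = top.phi_quads
        self.psi_quads = top.psi_quads
        self.weights = np.ascontiguousarray(top.helix_weights)
        self.hbond_pairs = top.hbond_pairs
        pairs = top.repulsion_pairs
        radii = params.role_radii()[top.atom_role]
        sig = radii[pairs[:, 0]] + radii[pairs[:, 1]]
        self.rep_pairs = pairs
        self.rep_sigma = np.ascontiguousarray(sig)
        self.rep_cutoff = np.ascontiguousarray(params.rep_cutoff_factor * sig)
        self.phi0 = np.deg2rad(params.phi0_deg)
        self.psi0 = np.deg2rad(params.psi0_deg)
        self.sigma_basin = np.deg2rad(params.sigma_basin_deg)

    def energy_forces(self, pos: np.ndarray):
        """Total potential; returns (per-term energies dict, forces)."""
        p = self.params
        forces = np.zeros_like(pos)
        e = {}
        e["bond"] = K.bond_ef(pos, self.bonds, self.bond_b0, p.k_bond, forces)
        e["angle"] = K.angle_ef(pos, self.angles, self.angle_theta0, p.k_angle, forces)
        e["omega"] = K.omega_ef(pos, self.omega_quads, p.k_omega, forces)
        e["torsion"] = K.torsion_basin_ef(
            pos, self.phi_quads, self.psi_quads, self.weights, p.eps_helix,
            self.phi0, self.psi0, self.sigma_basin, p.trans_bias,
            p.torsion_barrier3, forces)
        e["hbond"] = K.hbond_ef(pos, self.hbond_pairs, p.eps_hb, p.hb_d0,
                                p.hb_sigma, forces)
        e["repulsion"] = K.repulsion_ef(pos, self.rep_pairs, self.rep_sigma,
                                        self.rep_cutoff, p.eps_rep, forces)
        return e, forces


def _compiled(top: Topology, params: ForceFieldParams) -> CompiledForceField:
    # cache on the topology object: reuse across calls with same params
    cached = getattr(top, "_cff_cache", None)
    if cached is not None and cached.params is params:
        return cached
    cff = CompiledForceField(top, params)
    top._cff_cache = cff
    return cff


def bonded_energy_forces(conf: Conformation, top: Topology,
                         params: ForceFieldParams):
    """Harmonic bond + angle + omega-planarity energy and forces."""
    c = _compiled(top, params)
    pos = conf.positions
    forces = np.zeros_like(pos)
    e = K.bond_ef(pos, c.bonds, c.bond_b0, params.k_bond, forces)
    e += K.angle_ef(pos, c.angles, c.angle_theta0, params.k_angle, forces)
    e += K.omega_ef(pos, c.omega_quads, params.k_omega, forces)
    return e, forces


def torsion_energy_forces(conf: Conformation, top: Topology,
                          params: ForceFieldParams):
    """Helix-basin plus trans-bias torsion energy and forces.

    Angle arithmetic is periodic: shifting any dihedral by 360 degrees
    leaves the energy unchanged.
    """
    c = _compiled(top, params)
    pos = conf.positions
    forces = np.zeros_like(pos)
    e = K.torsion_basin_ef(pos, c.phi_quads, c.psi_quads, c.weights,
                           params.eps_helix, c.phi0, c.psi0, c.sigma_basin,
                           params.trans_bias, params.torsion_barrier3, forces)
    return e, forces


def hbond_energy_forces(conf: Conformation, top: Topology,
                        params: ForceFieldParams):
    c = _compiled(top, params)
    pos = conf.positions
    forces = np.zeros_like(pos)
    e = K.hbond_ef(pos, c.hbond_pairs, params.eps_hb, params.hb_d0,
                   params.hb_sigma, forces)
    return e, forces


def repulsion_energy_forces(conf: Conformation, top: Topology,
                            params: ForceFieldParams):
    c = _compiled(top, params)
    pos = conf.positions
    forces = np.zeros_like(pos)
    e = K.repulsion_ef(pos, c.rep_pairs, c.rep_sigma, c.rep_cutoff,
                       params.eps_rep, forces)
    return e, forces


def total_energy_forces(conf: Conformation, top: Topology,
                        params: ForceFieldParams):
    """Sum of all internal terms; per-term breakdown returned alongside."""
    c = _compiled(top, params)
    breakdown, forces = c.energy_forces(conf.positions)
    return sum(breakdown.values()), forces, breakdown


def numerical_gradient(potential: Callable[[np.ndarray], float],
                       positions: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central-difference negative gradient of a scalar potential.

    The independent oracle for every analytic force routine: one coordinate
    is displaced at a time, so the result never shares code with the
    analytic path it checks.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pos = np.array(positions, dtype=float)
    forces = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for d in range(pos.shape[1]):
            orig = pos[i, d]
            pos[i, d] = orig + step
            ep = potential(pos)
            pos[i, d] = orig - step
            em = potential(pos)
            pos[i, d] = orig
            forces[i, d] = -(ep - em) / (2.0 * step)
    return forces
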