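"""The folding-machine apparatus: enforced rotation plus terminal restraints.

The machine drags all coarse-grained atoms of the C-terminal residue
toward a reference frame that rotates about the +X axis at a fixed rate
(default 60 degrees/ps, force constant 1500 kJ/mol/nm^2), while

* the C-terminal O and N atoms are restrained in the YZ plane only
  (10000 kJ/mol/nm^2) so the driven residue can slide along the axis,
* the C-terminal O is weakly restrained along X (5 kJ/mol/nm^2), and
* the N-terminal N and CA atoms are restrained in all directions
  (10000 kJ/mol/nm^2).

The rotation term is the flexible-axis enforced-rotation potential in its
single-slab limit: the rotation group here is one residue (at most five
sites spanning well under half a nanometre along the axis), for which the
multi-slab machinery degenerates, while the single-slab form keeps the
defining behaviour -- a torque about the axis, no force component along
the axis, and a pivot-free (centroid-following) reference.

Handedness convention: "clockwise" labels the productive rotation sense,
the one that winds the backbone into the right-handed alpha helix.  With
the chain built N -> C along +X, that is the right-hand-rule sense about
+X (sign +1), i.e. clockwise when looking from the N-terminal anchor down
the axis toward the driven C terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .chain import Conformation, ROLE_CA, ROLE_N, ROLE_O, Topology
from .config import MachineParams

__all__ = ["MachineProtocol", "DriverRecord", "rotation_reference_positions",
           "rotation_energy_forces", "restraint_energy_forces",
           "accumulate_work"]


@dataclass
class DriverRecord:
    """One sample of the rotation driver: reference angle, torque, work."""

    time: float           # ps
    theta_deg: float      # reference angle s * omega * t
    torque: float         # kJ/mol (about the rotation axis)
    work: float           # kJ/mol accumulated


@dataclass
class MachineProtocol:
    """Resolved machine state for one run: constants, groups, and anchors.

    ``direction`` is +1/-1 in the internal right-hand-rule sense about +X;
    use :meth:`for_condition` to map the condition names.  Anchors and the
    rotation reference are captured from the starting conformation, which
    the chain builders place aligned with the X axis.
    """

    rotate: bool
    direction: int
    rate_deg_ps: float
    k_rot: float
    k_plane: float
    k_x: float
    k_fix: float
    group: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ref_rel: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    plane_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    plane_anchor: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    x_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    x_anchor: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    fix_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    fix_anchor: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        if self.rotate and abs(self.direction) != 1:
            raise ValueError("direction must be +1 or -1 when rotating")
        for k in (self.k_rot, self.k_plane, self.k_x, self.k_fix):
            if k < 0:
                raise ValueError("force constants must be >= 0")
        if self.rotate and self.group.size == 0:
            raise ValueError("rotation enabled but rotation group is empty")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_params(cls, params: MachineParams, top: Topology,
                    start: Conformation, rotate: bool, restrain: bool,
                    direction: int = 0) -> "MachineProtocol":
        """Capture groups and anchors from the starting conformation.

        ``direction`` is the internal sign; callers normally go through
        :meth:`for_condition` which applies the clockwise convention.
        """
        n_res = top.n_residues
        pos = start.positions
        if restrain:
            c_o = top.atom_index(n_res - 1, "O")
            c_n = top.atom_index(n_res - 1, "N")
            n_n = top.atom_index(0, "N")
            n_ca = top.atom_index(0, "CA")
            plane_idx = np.array([c_o, c_n], dtype=np.int64)
            x_idx = np.array([c_o], dtype=np.int64)
            fix_idx = np.array([n_n, n_ca], dtype=np.int64)
            kw = dict(
                plane_idx=plane_idx, plane_anchor=pos[plane_idx].copy(),
                x_idx=x_idx, x_anchor=pos[x_idx].copy(),
                fix_idx=fix_idx, fix_anchor=pos[fix_idx].copy(),
                k_plane=params.k_plane, k_x=params.k_x, k_fix=params.k_fix,
            )
        else:
            kw = dict(k_plane=0.0, k_x=0.0, k_fix=0.0)
        if rotate:
            group = top.residue_atoms(n_res - 1)
            ref = pos[group]
            kw.update(group=group, ref_rel=ref - ref.mean(axis=0))
        return cls(rotate=rotate, direction=direction,
                   rate_deg_ps=params.rate_deg_ps,
                   k_rot=params.k_rot if rotate else 0.0, **kw)

    @classmethod
    def for_condition(cls, name: str, params: MachineParams, top: Topology,
                      start: Conformation) -> "MachineProtocol":
        """Build the protocol for one of the four experiment conditions.

        free       -- no restraints, no rotation
        restrained -- terminal restraints only
        cw / ccw   -- restraints plus rotation; the two differ only in the
                      sign of the rotation direction
        """
        if name == "free":
            return cls.from_params(params, top, start, rotate=False, restrain=False)
        if name == "restrained":
            return cls.from_params(params, top, start, rotate=False, restrain=True)
        if name == "cw":
            return cls.from_params(params, top, start, rotate=True, restrain=True,
                                   direction=params.clockwise_sign)
        if name == "ccw":
            return cls.from_params(params, top, start, rotate=True, restrain=True,
                                   direction=-params.clockwise_sign)
        raise ValueError(f"unknown condition {name!r}")

    # -- evaluation --------------------------------------------------------

    @property
    def active(self) -> bool:
        return self.rotate or self.k_plane > 0 or self.k_x > 0 or self.k_fix > 0

    def theta(self, t: float) -> float:
        """Reference angle in radians at time t (ps): theta = s * omega * t."""
        return self.direction * np.deg2rad(self.rate_deg_ps) * t

    def energy_forces(self, pos: np.ndarray, t: float):
        """All machine contributions; returns (energy, forces, torque).

        Torque is measured from the rotation forces only (restraint forces
        excluded) and reported about the +X axis through the group centroid.
        """
        forces = np.zeros_like(pos)
        e = 0.0
        torque = 0.0
        if self.rotate:
            er, torque = K.rotation_ef(pos, self.group, self.ref_rel,
                                       self.theta(t), self.k_rot, forces)
            e += er
        e += K.restraint_ef(pos, self.plane_idx, self.plane_anchor, self.k_plane,
                            self.x_idx, self.x_anchor, self.k_x,
                            self.fix_idx, self.fix_anchor, self.k_fix, forces)
        return e, forces, torque


def rotation_reference_positions(t: float, protocol: MachineProtocol,
                                 reference_conf: Conformation) -> np.ndarray:
    """Rotated reference positions y_i(t) for the rotation group.

    y_i(t) = Omega(theta(t)) (y_i0 - y_c0) + y_c0 about the +X axis, where
    y_i0 are the group positions captured at t = 0.
    """
    ref = reference_conf.positions[protocol.group]
    c0 = ref.mean(axis=0)
    th = protocol.theta(t)
    ct, st = np.cos(th), np.sin(th)
    rel = ref - c0
    out = rel.copy()
    out[:, 1] = ct * rel[:, 1] - st * rel[:, 2]
    out[:, 2] = st * rel[:, 1] + ct * rel[:, 2]
    return out + c0


def rotation_energy_forces(conf: Conformation, t: float,
                           protocol: MachineProtocol):
    """Enforced-rotation term alone; returns (energy, forces, torque)."""
    if not protocol.rotate:
        raise ValueError("protocol has rotation disabled")
    forces = np.zeros_like(conf.positions)
    e, torque = K.rotation_ef(conf.positions, protocol.group, protocol.ref_rel,
                              protocol.theta(t), protocol.k_rot, forces)
    return e, forces, torque


def restraint_energy_forces(conf: Conformation, protocol: MachineProtocol):
    """Terminal restraints alone; returns (energy, forces)."""
    forces = np.zeros_like(conf.positions)
    e = K.restraint_ef(conf.positions, protocol.plane_idx, protocol.plane_anchor,
                       protocol.k_plane, protocol.x_idx, protocol.x_anchor,
                       protocol.k_x, protocol.fix_idx, protocol.fix_anchor,
                       protocol.k_fix, forces)
    return e, forces


def accumulate_work(torques: np.ndarray, dt: float,
                    protocol: MachineProtocol) -> np.ndarray:
    """Cumulative driver work W(t) = sum tau * s * omega * dt (kJ/mol).

    ``torques`` is a uniformly sampled torque series (sampling interval
    ``dt`` in ps); the angular rate is converted to radians so the product
    is an energy.
    """
    omega = np.deg2rad(protocol.rate_deg_ps)
    return np.cumsum(np.asarray(torques) * protocol.direction * omega * dt)
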