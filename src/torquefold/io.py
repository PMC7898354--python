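"""Structure and trajectory I/O: PDB via biotite, plain XYZ, TSV logs."""

from __future__ import annotations

from pathlib import Path

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
import numpy as np

from .chain import (Conformation, ROLE_CB, ROLE_NAMES, Sequence, Topology,
                    _place_cb, build_topology)
from .dynamics import Trajectory

__all__ = ["write_pdb", "read_reference_pdb", "write_xyz", "write_driver_log",
           "write_rmsd_log"]

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _atom_array(top: Topology, positions: np.ndarray) -> struc.AtomArray:
    n = top.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(positions) * 10.0  # nm -> Angstrom
    arr.chain_id = np.full(n, "A")
    arr.res_id = top.atom_res + 1
    letters = top.sequence.full
    arr.res_name = np.array([_THREE[letters[r]] for r in top.atom_res])
    names = np.array([ROLE_NAMES[r] for r in top.atom_role])
    arr.atom_name = names
    arr.element = np.array([_ELEMENT[x] for x in names])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb(path: str | Path, top: Topology,
              confs: Conformation | list[Conformation] | Trajectory) -> None:
    """Write one conformation or a multi-model trajectory as PDB."""
    if isinstance(confs, Trajectory):
        frames = [confs.positions[i] for i in range(confs.n_frames)]
    elif isinstance(confs, Conformation):
        frames = [confs.positions]
    else:
        frames = [c.positions for c in confs]
    f = pdbio.PDBFile()
    if len(frames) == 1:
        f.set_structure(_atom_array(top, frames[0]))
    else:
        stack = struc.stack([_atom_array(top, p) for p in frames])
        f.set_structure(stack)
    f.write(str(path))


def read_reference_pdb(path: str | Path, top: Topology,
                       res_id_range: tuple[int, int] | None = None) -> Conformation:
    """Read a native reference fragment onto an existing (core) topology.

    Coordinates are converted from Angstrom to nm and mapped onto the
    topology atom roles by atom name.  The selected residue range must be
    contiguous and match the topology length exactly.  A missing CB is
    tolerated (rebuilt from the backbone); a missing backbone atom is an
    error.
    """
    arr = pdbio.PDBFile.read(str(path)).get_structure(model=1)
    arr = arr[struc.filter_amino_acids(arr)]
    res_ids = np.unique(arr.res_id)
    if res_id_range is not None:
        lo, hi = res_id_range
        res_ids = res_ids[(res_ids >= lo) & (res_ids <= hi)]
    if len(res_ids) != top.n_residues:
        raise ValueError(
            f"selected fragment has {len(res_ids)} residues but the topology "
            f"has {top.n_residues}")
    pos = np.zeros((top.n_atoms, 3))
    for k, rid in enumerate(res_ids):
        res = arr[arr.res_id == rid]
        coords = {}
        for name in ("N", "CA", "C", "O"):
            sel = res[res.atom_name == name]
            if len(sel) == 0:
                raise ValueError(f"residue {rid} is missing backbone atom {name}")
            coords[name] = sel.coord[0] / 10.0
        for role, name in enumerate(("N", "CA", "C", "O")):
            pos[top.res_atom[k, role]] = coords[name]
        cb_idx = top.res_atom[k, ROLE_CB]
        if cb_idx >= 0:
            sel = res[res.atom_name == "CB"]
            if len(sel):
                pos[cb_idx] = sel.coord[0] / 10.0
            else:
                pos[cb_idx] = _place_cb(coords["N"], coords["CA"], coords["C"])
    return Conformation(pos, time=0.0)


def write_xyz(path: str | Path, top: Topology, traj: Trajectory) -> None:
    """Plain multi-frame XYZ; the comment line carries the time in ps."""
    names = top.atom_names
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{top.n_atoms}\n")
            fh.write(f"t = {traj.times[f]:.4f} ps\n")
            for name, (x, y, z) in zip(names, traj.positions[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def write_driver_log(path: str | Path, traj: Trajectory) -> None:
    """Tab-separated driver log: time, reference angle, torque, work."""
    with open(path, "w") as fh:
        fh.write("time_ps\ttheta_deg\ttorque_kj_mol\twork_kj_mol\n")
        for i in range(traj.n_frames):
            fh.write(f"{traj.times[i]:.4f}\t{traj.channels['theta_deg'][i]:.4f}\t"
                     f"{traj.channels['torque'][i]:.6f}\t"
                     f"{traj.channels['work'][i]:.6f}\n")


def write_rmsd_log(path: str | Path, times: np.ndarray, values: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("time_ps\trmsd_nm\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.4f}\t{v:.6f}\n")
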