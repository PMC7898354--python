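"""Folding metrics: superposed RMSD, first-passage times, dihedral series,
helicity, and rotation-propagation (chain winding) diagnostics.

RMSD is always computed over the backbone heavy atoms (N, CA, C, O) of the
core (non-handle) residues after an optimal rigid superposition; the two
alanine handles at each end receive the machine forces and are never
scored.  Folding is detected as the first passage of the core RMSD below a
threshold (default 0.2 nm) relative to the native reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .chain import Conformation, Topology
from .dynamics import Trajectory
from .machine import MachineProtocol

__all__ = [
    "RmsdSeries", "FoldingResult", "kabsch_superpose", "rmsd_series",
    "folding_time", "phi_psi_series", "helicity", "rotation_propagation",
    "summarize_runs",
]


@dataclass
class RmsdSeries:
    times: np.ndarray       # ps
    values: np.ndarray      # nm
    selection: str = "core backbone (N, CA, C, O)"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if np.any(self.values < 0):
            raise ValueError("rmsd values must be >= 0")


@dataclass
class FoldingResult:
    """Outcome of one run: first-passage folding time (or None) and final RMSD."""

    peptide: str
    condition: str
    seed: int
    folding_time_ps: float | None
    duration_ps: float
    final_rmsd_nm: float

    def __post_init__(self) -> None:
        if (self.folding_time_ps is not None
                and self.folding_time_ps > self.duration_ps + 1e-9):
            raise ValueError("folding time exceeds run duration")

    @property
    def folded(self) -> bool:
        return self.folding_time_ps is not None

    @property
    def cell(self) -> str:
        """Report-cell string 't/duration'; equal numbers mean no folding."""
        t = self.duration_ps if self.folding_time_ps is None else self.folding_time_ps
        return f"{_fmt(t)}/{_fmt(self.duration_ps)}"


def _fmt(x: float) -> str:
    return f"{x:g}"


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target``.  The
    rotation is always proper (determinant +1, no reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a superposition")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    a = mobile - mc
    b = target - tc
    if np.linalg.matrix_rank(a, tol=1e-10) < 2 or np.linalg.matrix_rank(b, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) selection")
    rot, _ = Rotation.align_vectors(b, a)
    rmat = rot.as_matrix()
    resid = a @ rmat.T - b
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    trans = tc - mc @ rmat.T
    return rmat, trans, rmsd


def rmsd_series(traj: Trajectory, native: np.ndarray,
                selection: np.ndarray) -> RmsdSeries:
    """Per-frame superposed RMSD of ``selection`` atoms against ``native``.

    ``native`` holds the reference coordinates for exactly the selected
    atoms (e.g. the core backbone of an ideal helix).
    """
    native = np.asarray(native, dtype=float)
    selection = np.asarray(selection, dtype=np.int64)
    if native.shape != (selection.size, 3):
        raise ValueError("native coordinates incongruent with selection")
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, vals[f] = kabsch_superpose(traj.positions[f][selection], native)
    return RmsdSeries(traj.times.copy(), vals)


def folding_time(series: RmsdSeries, threshold_nm: float = 0.2) -> float | None:
    """Time of the first frame with RMSD <= threshold; None if never reached."""
    if threshold_nm <= 0:
        raise ValueError("threshold must be positive")
    if series.values.size == 0:
        raise ValueError("empty RMSD series")
    hit = np.nonzero(series.values <= threshold_nm)[0]
    return float(series.times[hit[0]]) if hit.size else None


def _dihedrals_for_quads(pos: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed dihedrals (degrees, in (-180, 180]) for rows of atom quads."""
    p = pos[quads]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(b2 / np.linalg.norm(b2, axis=1, keepdims=True), n1)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    return np.rad2deg(np.arctan2(y, x))


def phi_psi_series(traj: Trajectory, top: Topology):
    """Backbone dihedral time series in degrees.

    Returns ``(phi, psi)`` arrays of shape (n_frames, n_residues) with NaN
    where the dihedral is undefined (phi of the first residue, psi of the
    last).  Standard conventions: phi = C_{i-1}-N-CA-C, psi = N-CA-C-N_{i+1}.
    """
    n_res = top.n_residues
    phi = np.full((traj.n_frames, n_res), np.nan)
    psi = np.full((traj.n_frames, n_res), np.nan)
    phi_ok = top.phi_quads[:, 0] >= 0
    psi_ok = top.psi_quads[:, 0] >= 0
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        phi[f, phi_ok] = _dihedrals_for_quads(pos, top.phi_quads[phi_ok])
        psi[f, psi_ok] = _dihedrals_for_quads(pos, top.psi_quads[psi_ok])
    return phi, psi


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + 180.0) % 360.0 - 180.0


def helicity(conf: Conformation, top: Topology,
             basin_radius_deg: float = 30.0,
             phi0: float = -57.0, psi0: float = -47.0) -> float:
    """Fraction of interior core residues inside the helix basin.

    A residue counts as helical when its (phi, psi) lies within
    ``basin_radius_deg`` (Euclidean distance in wrapped angle space) of the
    ideal-helix angles.  Only core residues with both dihedrals defined
    enter the denominator.
    """
    if basin_radius_deg <= 0:
        raise ValueError("basin_radius_deg must be positive")
    flags = top.handle_flags
    ok = (top.phi_quads[:, 0] >= 0) & (top.psi_quads[:, 0] >= 0) & ~flags
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        return 0.0
    pos = conf.positions
    phi = _dihedrals_for_quads(pos, top.phi_quads[idx])
    psi = _dihedrals_for_quads(pos, top.psi_quads[idx])
    d = np.hypot(_wrap(phi - phi0), _wrap(psi - psi0))
    return float(np.mean(d <= basin_radius_deg))


def rotation_propagation(traj: Trajectory, top: Topology) -> np.ndarray:
    """Per-residue cumulative CA winding angle about the chain axis (degrees).

    For each residue the azimuth of its CA about the axis through the
    N-terminal CA along +X is unwrapped over frames and reported relative
    to the first frame, quantifying how much net rotation the driven end
    transmits down the chain.  Frames must be dense enough that per-frame
    azimuth increments stay below 180 degrees.
    """
    ca = top.res_atom[:, 1]
    anchor = traj.positions[:, ca[0], 1:]          # (F, 2) y, z of N-term CA
    rel = traj.positions[:, ca, 1:] - anchor[:, None, :]
    az = np.arctan2(rel[:, :, 1], rel[:, :, 0])    # (F, n_res)
    steps = np.diff(az, axis=0)
    steps = (steps + np.pi) % (2 * np.pi) - np.pi
    # the anchor residue sits on the axis; its azimuth is noise, zero it
    steps[:, 0] = 0.0
    if np.any(np.abs(steps) >= np.pi - 1e-9):
        raise ValueError(
            "azimuth increment of 180 degrees or more between frames; "
            "use a finer reporting interval")
    out = np.zeros_like(az)
    out[1:] = np.cumsum(steps, axis=0)
    return np.rad2deg(out)


def summarize_runs(results: list[FoldingResult],
                   condition_order: tuple[str, ...] = ("free", "restrained",
                                                       "cw", "ccw")) -> pd.DataFrame:
    """Per-peptide x per-condition summary table.

    One row per peptide; for each condition a cell of space-separated
    ``t/duration`` strings (replicate order), where equal numerator and
    denominator encode "folding not observed", plus per-condition median
    folding time and fold fraction columns.
    """
    if not results:
        raise ValueError("no results to summarize")
    rows = {}
    for r in results:
        rows.setdefault(r.peptide, {}).setdefault(r.condition, []).append(r)
    records = []
    for pid in rows:
        rec: dict[str, object] = {"peptide": pid}
        for cond in condition_order:
            runs = sorted(rows[pid].get(cond, []), key=lambda r: r.seed)
            rec[cond] = " ".join(r.cell for r in runs) if runs else ""
            times = [r.folding_time_ps for r in runs if r.folded]
            rec[f"{cond}_median_fold_ps"] = float(np.median(times)) if times else np.nan
            rec[f"{cond}_fold_fraction"] = (
                len(times) / len(runs) if runs else np.nan)
        records.append(rec)
    df = pd.DataFrame.from_records(records).set_index("peptide")
    cols = list(condition_order)
    cols += [c for c in df.columns if c not in cols]
    return df[cols]
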