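"""Peptide chain construction for the coarse-grained folding-machine model.

A peptide is represented with five interaction sites per residue -- the
backbone heavy atoms N, CA, C, O plus a single side-chain bead CB carrying
the whole side-chain mass (glycine has no CB).  This is the smallest
representation that still defines the phi/psi/omega backbone dihedrals,
carbonyl-based i -> i+4 hydrogen bonds, and side-chain sterics.

The module parses one-letter sequences (including repeat notation such as
``AAAA(AAARA)3``), attaches the two terminal alanine "handle" residues at
each end that receive the machine forces, enumerates the bonded topology,
and builds deterministic starting/reference conformations: a stretched
chain aligned with the X axis and an ideal right-handed alpha helix at
(phi, psi) = (-57, -47) degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np

__all__ = [
    "AA_LETTERS",
    "Sequence",
    "Conformation",
    "Topology",
    "expand_sequence_notation",
    "add_handles",
    "build_topology",
    "build_extended_conformation",
    "build_ideal_helix",
    "HELIX_PHI_DEG",
    "HELIX_PSI_DEG",
]

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

# Lumped side-chain masses (amu) for the CB bead; backbone sites carry
# N(+H)=15.01, CA(+H)=13.02, C=12.01, O=16.00.
SIDECHAIN_MASS = {
    "A": 15.03, "R": 100.14, "N": 58.06, "D": 59.04, "C": 47.10,
    "Q": 72.09, "E": 73.07, "G": 0.0, "H": 81.10, "I": 57.12,
    "K": 72.13, "L": 57.12, "M": 75.15, "F": 91.13, "P": 41.07,
    "S": 31.03, "T": 45.06, "V": 43.09, "W": 130.17, "Y": 107.13,
}

BACKBONE_MASS = {"N": 15.01, "CA": 13.02, "C": 12.01, "O": 16.00}

# Atom-role codes used throughout the package.
ROLE_N, ROLE_CA, ROLE_C, ROLE_O, ROLE_CB = 0, 1, 2, 3, 4
ROLE_NAMES = ("N", "CA", "C", "O", "CB")

# Equilibrium backbone geometry (nm / degrees).  Conventional peptide
# values; the chain builders generate coordinates at exactly these values
# so freshly built structures sit at the bonded-energy minimum.
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1231
BOND_CA_CB = 0.1530

ANG_N_CA_C = 111.0
ANG_CA_C_N = 116.6
ANG_C_N_CA = 121.9
ANG_CA_C_O = 120.8
ANG_O_C_N = 122.6  # = 360 - ANG_CA_C_N - ANG_CA_C_O (planar carbonyl)
ANG_N_CA_CB = 110.5
ANG_CB_CA_C = 110.1

HELIX_PHI_DEG = -57.0
HELIX_PSI_DEG = -47.0


class SequenceError(ValueError):
    """Raised for malformed sequence notation or invalid residue letters."""


def expand_sequence_notation(notation: str) -> str:
    """Expand repeat notation like ``"AAAA(AAARA)3"`` into a flat sequence.

    A parenthesised block followed by a positive integer is repeated that
    many times; expansion proceeds left to right and supports nesting
    depth 1.  Residue-letter validity is checked later by :class:`Sequence`,
    so this is a pure string operation.
    """
    out: list[str] = []
    i = 0
    n = len(notation)
    while i < n:
        ch = notation[i]
        if ch == "(":
            j = notation.find(")", i + 1)
            if j < 0:
                raise SequenceError(f"unbalanced '(' in {notation!r}")
            block = notation[i + 1 : j]
            if "(" in block:
                raise SequenceError("nested repeat groups are not supported")
            k = j + 1
            while k < n and notation[k].isdigit():
                k += 1
            if k == j + 1:
                raise SequenceError(f"repeat group missing count in {notation!r}")
            count = int(notation[j + 1 : k])
            if count == 0:
                raise SequenceError("repeat count must be >= 1")
            out.append(block * count)
            i = k
        elif ch == ")":
            raise SequenceError(f"unbalanced ')' in {notation!r}")
        elif ch.isdigit():
            raise SequenceError(f"stray digit outside repeat group in {notation!r}")
        else:
            out.append(ch)
            i += 1
    return "".join(out)


@dataclass(frozen=True)
class Sequence:
    """An amino-acid sequence with optional terminal alanine handles.

    ``core`` is the sequence of interest; ``handles_per_end`` alanines are
    attached at each terminus to receive the machine restraints/rotation.
    Handles are excluded from RMSD scoring downstream.
    """

    core: str
    handles_per_end: int = 0

    def __post_init__(self) -> None:
        if len(self.core) < 1:
            raise SequenceError("core sequence must contain at least one residue")
        bad = sorted(set(self.core) - set(AA_LETTERS))
        if bad:
            raise SequenceError(f"invalid residue letters: {bad}")
        if self.handles_per_end < 0:
            raise SequenceError("handles_per_end must be >= 0")

    @property
    def full(self) -> str:
        h = "A" * self.handles_per_end
        return h + self.core + h

    @property
    def n_residues(self) -> int:
        return len(self.full)

    @property
    def handle_flags(self) -> np.ndarray:
        """Boolean flag per residue of the full sequence; True for handles."""
        flags = np.zeros(self.n_residues, dtype=bool)
        h = self.handles_per_end
        if h:
            flags[:h] = True
            flags[-h:] = True
        return flags

    @classmethod
    def from_notation(cls, notation: str, handles_per_end: int = 0) -> "Sequence":
        return cls(expand_sequence_notation(notation), handles_per_end)


def add_handles(seq: Sequence, per_end: int = 2) -> Sequence:
    """Attach ``per_end`` alanine handle residues to each terminus.

    Applying handles twice would silently bury the original handles inside
    the scored region, so a sequence that already has handles is rejected.
    """
    if seq.handles_per_end != 0:
        raise SequenceError("sequence already has handles; refusing to add more")
    if per_end < 1:
        raise SequenceError("per_end must be >= 1")
    return replace(seq, handles_per_end=per_end)


@dataclass
class Conformation:
    """Cartesian coordinates (nm) for every topology atom at one time (ps)."""

    positions: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(self.positions.copy(), self.time)


@dataclass
class Topology:
    """Coarse-grained topology: atoms, bonded terms, and H-bond pairs.

    Equilibrium geometry lives here (per-term ``b0`` / ``theta0``); the
    stiffnesses are force-field parameters and are supplied separately.
    Quad rows equal to -1 mark torsions that are undefined at the chain
    ends (phi of the first residue, psi/omega of the last).
    """

    sequence: Sequence
    atom_res: np.ndarray          # (n_atoms,) residue index
    atom_role: np.ndarray         # (n_atoms,) role code
    masses: np.ndarray            # (n_atoms,) amu
    res_atom: np.ndarray          # (n_res, 5) atom index per role, -1 if absent
    bonds: np.ndarray             # (B, 2)
    bond_b0: np.ndarray           # (B,)
    angles: np.ndarray            # (A, 3)
    angle_theta0: np.ndarray      # (A,) radians
    omega_quads: np.ndarray       # (n_res-1, 4) CA-C-N'-CA'
    phi_quads: np.ndarray         # (n_res, 4) C_{i-1}-N-CA-C, row -1 if undefined
    psi_quads: np.ndarray         # (n_res, 4) N-CA-C-N_{i+1}, row -1 if undefined
    hbond_pairs: np.ndarray       # (H, 2) O_i, N_{i+4}

    @property
    def n_atoms(self) -> int:
        return self.atom_res.shape[0]

    @property
    def n_residues(self) -> int:
        return self.sequence.n_residues

    @property
    def handle_flags(self) -> np.ndarray:
        return self.sequence.handle_flags

    @cached_property
    def helix_weights(self) -> np.ndarray:
        from .config import HELIX_PROPENSITY

        return np.array([HELIX_PROPENSITY[r] for r in self.sequence.full])

    @cached_property
    def bond_graph_distance_le2(self) -> np.ndarray:
        """Pairs (i, j), i<j, separated by at most 2 bonds (excluded pairs)."""
        n = self.n_atoms
        adj: list[set[int]] = [set() for _ in range(n)]
        for a, b in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        excl = set()
        for i in range(n):
            for j in adj[i]:
                excl.add((min(i, j), max(i, j)))
                for k in adj[j]:
                    if k != i:
                        excl.add((min(i, k), max(i, k)))
        return np.array(sorted(excl), dtype=np.int64)

    @cached_property
    def repulsion_pairs(self) -> np.ndarray:
        """All atom pairs more than 2 bonds apart (steric interaction list)."""
        n = self.n_atoms
        ii, jj = np.triu_indices(n, k=1)
        excl = {tuple(p) for p in self.bond_graph_distance_le2}
        keep = [m for m in range(ii.size) if (ii[m], jj[m]) not in excl]
        return np.stack([ii[keep], jj[keep]], axis=1).astype(np.int64)

    def atom_index(self, residue: int, role: str) -> int:
        idx = int(self.res_atom[residue, ROLE_NAMES.index(role)])
        if idx < 0:
            raise KeyError(f"residue {residue} has no {role} atom")
        return idx

    def backbone_atom_indices(self, core_only: bool = True) -> np.ndarray:
        """Indices of backbone N, CA, C, O atoms, optionally core residues only.

        This is the default RMSD selection: the handle residues never enter
        the RMSD because they are not part of the sequence whose folding is
        scored.
        """
        flags = self.handle_flags
        res_sel = np.nonzero(~flags)[0] if core_only else np.arange(self.n_residues)
        cols = [ROLE_N, ROLE_CA, ROLE_C, ROLE_O]
        idx = self.res_atom[np.ix_(res_sel, cols)].ravel()
        return idx[idx >= 0].astype(np.int64)

    def residue_atoms(self, residue: int) -> np.ndarray:
        return np.nonzero(self.atom_res == residue)[0].astype(np.int64)

    @property
    def atom_names(self) -> list[str]:
        return [ROLE_NAMES[r] for r in self.atom_role]


def build_topology(seq: Sequence) -> Topology:
    """Enumerate atoms, bonded terms, torsion quads, and H-bond pairs.

    Five sites per residue (four for glycine, which has no CB); one
    O_i -> N_{i+4} hydrogen-bond pair for every residue with a partner in
    range.
    """
    letters = seq.full
    n_res = len(letters)
    res_atom = -np.ones((n_res, 5), dtype=np.int64)
    atom_res: list[int] = []
    atom_role: list[int] = []
    masses: list[float] = []

    for i, aa in enumerate(letters):
        roles = [ROLE_N, ROLE_CA, ROLE_C, ROLE_O]
        if aa != "G":
            roles.append(ROLE_CB)
        for role in roles:
            res_atom[i, role] = len(atom_res)
            atom_res.append(i)
            atom_role.append(role)
            masses.append(
                SIDECHAIN_MASS[aa] if role == ROLE_CB else BACKBONE_MASS[ROLE_NAMES[role]]
            )

    bonds: list[tuple[int, int]] = []
    b0: list[float] = []
    angles: list[tuple[int, int, int]] = []
    th0: list[float] = []

    def A(i: int, role: int) -> int:
        return int(res_atom[i, role])

    for i in range(n_res):
        bonds += [(A(i, ROLE_N), A(i, ROLE_CA)), (A(i, ROLE_CA), A(i, ROLE_C)),
                  (A(i, ROLE_C), A(i, ROLE_O))]
        b0 += [BOND_N_CA, BOND_CA_C, BOND_C_O]
        angles += [(A(i, ROLE_N), A(i, ROLE_CA), A(i, ROLE_C)),
                   (A(i, ROLE_CA), A(i, ROLE_C), A(i, ROLE_O))]
        th0 += [ANG_N_CA_C, ANG_CA_C_O]
        if res_atom[i, ROLE_CB] >= 0:
            bonds.append((A(i, ROLE_CA), A(i, ROLE_CB)))
            b0.append(BOND_CA_CB)
            angles += [(A(i, ROLE_N), A(i, ROLE_CA), A(i, ROLE_CB)),
                       (A(i, ROLE_CB), A(i, ROLE_CA), A(i, ROLE_C))]
            th0 += [ANG_N_CA_CB, ANG_CB_CA_C]
        if i + 1 < n_res:
            bonds.append((A(i, ROLE_C), A(i + 1, ROLE_N)))
            b0.append(BOND_C_N)
            angles += [(A(i, ROLE_CA), A(i, ROLE_C), A(i + 1, ROLE_N)),
                       (A(i, ROLE_O), A(i, ROLE_C), A(i + 1, ROLE_N)),
                       (A(i, ROLE_C), A(i + 1, ROLE_N), A(i + 1, ROLE_CA))]
            th0 += [ANG_CA_C_N, ANG_O_C_N, ANG_C_N_CA]

    omega = np.array(
        [(A(i, ROLE_CA), A(i, ROLE_C), A(i + 1, ROLE_N), A(i + 1, ROLE_CA))
         for i in range(n_res - 1)],
        dtype=np.int64,
    ).reshape(-1, 4)

    phi = -np.ones((n_res, 4), dtype=np.int64)
    psi = -np.ones((n_res, 4), dtype=np.int64)
    for i in range(n_res):
        if i > 0:
            phi[i] = (A(i - 1, ROLE_C), A(i, ROLE_N), A(i, ROLE_CA), A(i, ROLE_C))
        if i + 1 < n_res:
            psi[i] = (A(i, ROLE_N), A(i, ROLE_CA), A(i, ROLE_C), A(i + 1, ROLE_N))

    hb = np.array(
        [(A(i, ROLE_O), A(i + 4, ROLE_N)) for i in range(n_res - 4)],
        dtype=np.int64,
    ).reshape(-1, 2)

    return Topology(
        sequence=seq,
        atom_res=np.array(atom_res, dtype=np.int64),
        atom_role=np.array(atom_role, dtype=np.int64),
        masses=np.array(masses),
        res_atom=res_atom,
        bonds=np.array(bonds, dtype=np.int64),
        bond_b0=np.array(b0),
        angles=np.array(angles, dtype=np.int64),
        angle_theta0=np.deg2rad(np.array(th0)),
        omega_quads=omega,
        phi_quads=phi,
        psi_quads=psi,
        hbond_pairs=hb,
    )


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          r: float, theta_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d with |c-d| = r, angle(b,c,d) = theta, tau(a,b,c,d) = dihedral."""
    theta = np.deg2rad(theta_deg)
    tau = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -r * np.cos(theta),
        r * np.sin(theta) * np.cos(tau),
        r * np.sin(theta) * np.sin(tau),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_cb(n_pos: np.ndarray, ca: np.ndarray, c_pos: np.ndarray) -> np.ndarray:
    """Side-chain bead position with exact N-CA-CB / CB-CA-C angles, L chirality."""
    u = n_pos - ca
    u /= np.linalg.norm(u)
    v = c_pos - ca
    v /= np.linalg.norm(v)
    cos_uv = float(u @ v)
    cu = np.cos(np.deg2rad(ANG_N_CA_CB))
    cv = np.cos(np.deg2rad(ANG_CB_CA_C))
    # w = alpha*u + beta*v + gamma*(u x v)/|u x v|, solve for exact angles
    det = 1.0 - cos_uv**2
    alpha = (cu - cv * cos_uv) / det
    beta = (cv - cu * cos_uv) / det
    rest = 1.0 - (alpha**2 + beta**2 + 2 * alpha * beta * cos_uv)
    gamma = np.sqrt(max(rest, 0.0))
    perp = np.cross(u, v)
    perp /= np.linalg.norm(perp)
    # negative gamma gives the L-amino-acid branch for this site ordering
    w = alpha * u + beta * v - gamma * perp
    return ca + BOND_CA_CB * w


def _build_chain(top: Topology, phi_deg: np.ndarray, psi_deg: np.ndarray,
                 omega_deg: float = 180.0) -> np.ndarray:
    """Construct coordinates from internal coordinates (NeRF), then align to X.

    The Calpha trace is aligned with the +X axis (least-squares line through
    the Calpha positions), with the N terminus at low x and the lateral
    centroid on the axis, matching the machine convention that the rotation
    axis is +X through the chain.
    """
    n_res = top.n_residues
    pos = np.zeros((top.n_atoms, 3))

    def put(i: int, role: int, xyz: np.ndarray) -> None:
        pos[top.res_atom[i, role]] = xyz

    def get(i: int, role: int) -> np.ndarray:
        return pos[top.res_atom[i, role]]

    # seed residue 0
    put(0, ROLE_N, np.zeros(3))
    put(0, ROLE_CA, np.array([BOND_N_CA, 0.0, 0.0]))
    ang = np.deg2rad(ANG_N_CA_C)
    put(0, ROLE_C, get(0, ROLE_CA) + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0]))

    for i in range(n_res):
        if i > 0:
            put(i, ROLE_C, _nerf(get(i - 1, ROLE_C), get(i, ROLE_N), get(i, ROLE_CA),
                                 BOND_CA_C, ANG_N_CA_C, phi_deg[i]))
        if i + 1 < n_res:
            put(i + 1, ROLE_N, _nerf(get(i, ROLE_N), get(i, ROLE_CA), get(i, ROLE_C),
                                     BOND_C_N, ANG_CA_C_N, psi_deg[i]))
            put(i + 1, ROLE_CA, _nerf(get(i, ROLE_CA), get(i, ROLE_C), get(i + 1, ROLE_N),
                                      BOND_N_CA, ANG_C_N_CA, omega_deg))
            o_dihedral = psi_deg[i] - 180.0
        else:
            o_dihedral = 0.0
        put(i, ROLE_O, _nerf(get(i, ROLE_N), get(i, ROLE_CA), get(i, ROLE_C),
                             BOND_C_O, ANG_CA_C_O, o_dihedral))
        if top.res_atom[i, ROLE_CB] >= 0:
            put(i, ROLE_CB, _place_cb(get(i, ROLE_N), get(i, ROLE_CA), get(i, ROLE_C)))

    return _align_to_x(pos, top)


def _align_to_x(pos: np.ndarray, top: Topology) -> np.ndarray:
    """Rigidly move the chain so the Calpha axis runs along +X, N terminus first."""
    ca_idx = top.res_atom[:, ROLE_CA]
    ca = pos[ca_idx]
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    # rotation taking `axis` to +X (minimal rotation)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, x)
    s = np.linalg.norm(v)
    c = float(axis @ x)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    out = (pos - center) @ rot.T
    # put lateral centroid on the axis and the N-terminal CA at x = 0
    out[:, 0] -= out[ca_idx[0], 0]
    return out


def build_extended_conformation(top: Topology) -> Conformation:
    """Stretched all-trans starting structure aligned with the X axis.

    Every bond, angle, and omega torsion sits exactly at its equilibrium
    value, so the bonded energy of the result is zero to rounding.
    """
    n = top.n_residues
    trans = np.full(n, 180.0)
    return Conformation(_build_chain(top, trans, trans), time=0.0)


def build_ideal_helix(top: Topology, core_only: bool = False):
    """Ideal right-handed alpha helix at (phi, psi) = (-57, -47) degrees.

    Used as the default native reference when no experimental fragment is
    supplied.  With ``core_only`` the conformation is returned together
    with the core backbone atom selection (handles excluded), which is the
    form consumed by the RMSD machinery.
    """
    n = top.n_residues
    conf = Conformation(_build_chain(top, np.full(n, HELIX_PHI_DEG),
                                     np.full(n, HELIX_PSI_DEG)), time=0.0)
    if core_only:
        sel = top.backbone_atom_indices(core_only=True)
        return conf, sel
    return conf
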