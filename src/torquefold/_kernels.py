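"""Numba-compiled inner loops for the energy terms and machine forces.

Every routine accumulates forces in place and returns the term energy.
All analytic gradients are validated against a central-difference oracle
in the test suite, so these kernels are the single implementation of the
model physics (no separate "fast path").

Units: nm, ps, amu, kJ/mol; angles in radians inside the kernels.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def bond_ef(pos, pairs, b0, k, forces):
    e = 0.0
    for m in range(pairs.shape[0]):
        i, j = pairs[m, 0], pairs[m, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - b0[m]
        e += 0.5 * k * dr * dr
        f = -k * dr / r
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
    return e


@njit(cache=True)
def angle_ef(pos, triples, th0, k, forces):
    e = 0.0
    for m in range(triples.shape[0]):
        i, j, l = triples[m, 0], triples[m, 1], triples[m, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[l, 0] - pos[j, 0]
        vy = pos[l, 1] - pos[j, 1]
        vz = pos[l, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        dth = th - th0[m]
        e += 0.5 * k * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        coef = k * dth / s  # -dE/dtheta * dtheta/dcos = (k dtheta / s)
        inuv = 1.0 / (nu * nv)
        inu2 = c / (nu * nu)
        inv2 = c / (nv * nv)
        # dcos/du = v/(nu*nv) - c*u/nu^2 ; dcos/dv symmetric
        fix = coef * (vx * inuv - ux * inu2)
        fiy = coef * (vy * inuv - uy * inu2)
        fiz = coef * (vz * inuv - uz * inu2)
        flx = coef * (ux * inuv - vx * inv2)
        fly = coef * (uy * inuv - vy * inv2)
        flz = coef * (uz * inuv - vz * inv2)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[l, 0] += flx
        forces[l, 1] += fly
        forces[l, 2] += flz
        forces[j, 0] -= fix + flx
        forces[j, 1] -= fiy + fly
        forces[j, 2] -= fiz + flz
    return e


@njit(cache=True, inline="always")
def _dihedral_and_grads(pos, i, j, k, l, grad):
    """Signed dihedral (IUPAC, cis = 0) and d(phi)/dx for the four atoms.

    grad has shape (4, 3) and is overwritten.
    Returns the dihedral in (-pi, pi].  Scalar arithmetic throughout: this
    sits on the innermost path of the integrator.
    """
    b1x = pos[j, 0] - pos[i, 0]
    b1y = pos[j, 1] - pos[i, 1]
    b1z = pos[j, 2] - pos[i, 2]
    b2x = pos[k, 0] - pos[j, 0]
    b2y = pos[k, 1] - pos[j, 1]
    b2z = pos[k, 2] - pos[j, 2]
    b3x = pos[l, 0] - pos[k, 0]
    b3y = pos[l, 1] - pos[k, 1]
    b3z = pos[l, 2] - pos[k, 2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    x = n1x * n2x + n1y * n2y + n1z * n2z
    # m1 = (b2/|b2|) x n1
    m1x = (b2y * n1z - b2z * n1y) / nb2
    m1y = (b2z * n1x - b2x * n1z) / nb2
    m1z = (b2x * n1y - b2y * n1x) / nb2
    y = m1x * n2x + m1y * n2y + m1z * n2z
    phi = np.arctan2(y, x)

    n1sq = n1x * n1x + n1y * n1y + n1z * n1z
    n2sq = n2x * n2x + n2y * n2y + n2z * n2z
    if n1sq < 1e-14:
        n1sq = 1e-14
    if n2sq < 1e-14:
        n2sq = 1e-14
    a1 = -nb2 / n1sq
    a4 = nb2 / n2sq
    t1x = a1 * n1x
    t1y = a1 * n1y
    t1z = a1 * n1z
    t4x = a4 * n2x
    t4y = a4 * n2y
    t4z = a4 * n2z
    inb2sq = 1.0 / (nb2 * nb2)
    p = (b1x * b2x + b1y * b2y + b1z * b2z) * inb2sq
    q = (b3x * b2x + b3y * b2y + b3z * b2z) * inb2sq
    grad[0, 0] = t1x
    grad[0, 1] = t1y
    grad[0, 2] = t1z
    grad[1, 0] = -(1.0 + p) * t1x + q * t4x
    grad[1, 1] = -(1.0 + p) * t1y + q * t4y
    grad[1, 2] = -(1.0 + p) * t1z + q * t4z
    grad[2, 0] = p * t1x - (1.0 + q) * t4x
    grad[2, 1] = p * t1y - (1.0 + q) * t4y
    grad[2, 2] = p * t1z - (1.0 + q) * t4z
    grad[3, 0] = t4x
    grad[3, 1] = t4y
    grad[3, 2] = t4z
    return phi


@njit(cache=True)
def dihedral_value(pos, i, j, k, l):
    g = np.empty((4, 3))
    return _dihedral_and_grads(pos, i, j, k, l, g)


@njit(cache=True)
def omega_ef(pos, quads, k, forces):
    """Harmonic planarity about omega = 180 degrees, periodic difference."""
    e = 0.0
    g = np.empty((4, 3))
    for m in range(quads.shape[0]):
        i, j, kk, l = quads[m, 0], quads[m, 1], quads[m, 2], quads[m, 3]
        w = _dihedral_and_grads(pos, i, j, kk, l, g)
        dw = w - np.pi
        while dw <= -np.pi:
            dw += TWO_PI
        while dw > np.pi:
            dw -= TWO_PI
        e += 0.5 * k * dw * dw
        coef = -k * dw
        for a, atom in enumerate((i, j, kk, l)):
            for d in range(3):
                forces[atom, d] += coef * g[a, d]
    return e


@njit(cache=True)
def torsion_basin_ef(pos, phi_quads, psi_quads, weights, eps_helix,
                     phi0, psi0, sigma, trans_bias, barrier3, forces):
    """Helix basin on (phi, psi) plus background torsion terms.

    Basin: -eps_helix * w_r * exp(-[(dphi)^2 + (dpsi)^2] / (2 sigma^2)) for
    every residue with both dihedrals defined; differences are wrapped at
    +/- pi.  Background per defined phi/psi: (trans_bias/2) * (1 + cos a),
    a gentle preference for extended backbone, plus a 3-fold rotation
    barrier (barrier3/2) * (1 + cos 3a) with maxima at 0 and +/-120 degrees
    and minima at 180 and +/-60.  The 3-fold term is what makes backbone
    rotation ratchet-like: a torsion forced over the -120 barrier settles
    near the helix angles and stays there, so further twist from the driven
    end must propagate to the next residue instead of spinning one bond.
    """
    e = 0.0
    gphi = np.empty((4, 3))
    gpsi = np.empty((4, 3))
    n_res = phi_quads.shape[0]
    for r in range(n_res):
        has_phi = phi_quads[r, 0] >= 0
        has_psi = psi_quads[r, 0] >= 0
        phi = 0.0
        psi = 0.0
        if has_phi:
            phi = _dihedral_and_grads(pos, phi_quads[r, 0], phi_quads[r, 1],
                                      phi_quads[r, 2], phi_quads[r, 3], gphi)
        if has_psi:
            psi = _dihedral_and_grads(pos, psi_quads[r, 0], psi_quads[r, 1],
                                      psi_quads[r, 2], psi_quads[r, 3], gpsi)
        # background terms: trans bias (1-fold) + rotation barrier (3-fold)
        if has_phi:
            e += 0.5 * trans_bias * (1.0 + np.cos(phi))
            e += 0.5 * barrier3 * (1.0 + np.cos(3.0 * phi))
            coef = 0.5 * trans_bias * np.sin(phi) + 1.5 * barrier3 * np.sin(3.0 * phi)
            for a in range(4):
                for d in range(3):
                    forces[phi_quads[r, a], d] += coef * gphi[a, d]
        if has_psi:
            e += 0.5 * trans_bias * (1.0 + np.cos(psi))
            e += 0.5 * barrier3 * (1.0 + np.cos(3.0 * psi))
            coef = 0.5 * trans_bias * np.sin(psi) + 1.5 * barrier3 * np.sin(3.0 * psi)
            for a in range(4):
                for d in range(3):
                    forces[psi_quads[r, a], d] += coef * gpsi[a, d]
        if not (has_phi and has_psi):
            continue
        dphi = phi - phi0
        while dphi <= -np.pi:
            dphi += TWO_PI
        while dphi > np.pi:
            dphi -= TWO_PI
        dpsi = psi - psi0
        while dpsi <= -np.pi:
            dpsi += TWO_PI
        while dpsi > np.pi:
            dpsi -= TWO_PI
        amp = eps_helix * weights[r]
        eb = -amp * np.exp(-(dphi * dphi + dpsi * dpsi) / (2.0 * sigma * sigma))
        e += eb
        # dE/dphi = -eb * dphi / sigma^2  (eb negative)
        cphi = eb * dphi / (sigma * sigma)   # -dE/dphi
        cpsi = eb * dpsi / (sigma * sigma)
        for a in range(4):
            for d in range(3):
                forces[phi_quads[r, a], d] += cphi * gphi[a, d]
                forces[psi_quads[r, a], d] += cpsi * gpsi[a, d]
    return e


@njit(cache=True)
def hbond_ef(pos, pairs, eps, d0, sigma, forces):
    e = 0.0
    for m in range(pairs.shape[0]):
        i, j = pairs[m, 0], pairs[m, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - d0
        ei = -eps * np.exp(-dr * dr / (2.0 * sigma * sigma))
        e += ei
        # dE/dr = -ei * dr / sigma^2 ; force on j along +rhat is -dE/dr
        f = ei * dr / (sigma * sigma) / r
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
    return e


@njit(cache=True)
def repulsion_ef(pos, pairs, sig, cutoff, eps, forces):
    """Truncated-and-shifted r^-12 repulsion; zero at and beyond the cutoff."""
    e = 0.0
    for m in range(pairs.shape[0]):
        i, j = pairs[m, 0], pairs[m, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        rc = cutoff[m]
        if r2 >= rc * rc:
            continue
        r = np.sqrt(r2)
        sr = sig[m] / r
        src = sig[m] / rc
        sr12 = sr ** 12
        e += eps * (sr12 - src ** 12)
        f = 12.0 * eps * sr12 / r2  # (1/r) * 12 eps sr12 / r, applied to dx
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
    return e


@njit(cache=True)
def rotation_ef(pos, group, ref_rel, theta, k_rot, forces):
    """Single-slab flexible-axis enforced rotation about +X.

    V = k/2 * sum_i || P_perp [ x_i - x_c - Omega(theta) u_i ] ||^2 with
    x_c the current group centroid, u_i the initial positions relative to
    the initial centroid, and P_perp removing the X component.  Forces have
    no X component and sum to zero over the group (pivot-free centroid).

    Returns (energy, torque about +X through the group centroid).
    """
    ng = group.shape[0]
    ct = np.cos(theta)
    st = np.sin(theta)
    # current centroid
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for a in range(ng):
        i = group[a]
        cx += pos[i, 0]
        cy += pos[i, 1]
        cz += pos[i, 2]
    cx /= ng
    cy /= ng
    cz /= ng
    dy = np.empty(ng)
    dz = np.empty(ng)
    my = 0.0
    mz = 0.0
    e = 0.0
    for a in range(ng):
        i = group[a]
        # rotate reference about +X: (y, z) -> (c y - s z, s y + c z)
        ry = ct * ref_rel[a, 1] - st * ref_rel[a, 2]
        rz = st * ref_rel[a, 1] + ct * ref_rel[a, 2]
        dy[a] = pos[i, 1] - cy - ry
        dz[a] = pos[i, 2] - cz - rz
        e += 0.5 * k_rot * (dy[a] * dy[a] + dz[a] * dz[a])
        my += dy[a]
        mz += dz[a]
    my /= ng
    mz /= ng
    torque = 0.0
    for a in range(ng):
        i = group[a]
        fy = -k_rot * (dy[a] - my)
        fz = -k_rot * (dz[a] - mz)
        forces[i, 1] += fy
        forces[i, 2] += fz
        # torque about +X through centroid: r x F, x-component
        torque += (pos[i, 1] - cy) * fz - (pos[i, 2] - cz) * fy
    return e, torque


@njit(cache=True)
def restraint_ef(pos, plane_idx, plane_anchor, k_plane,
                 x_idx, x_anchor, k_x, fix_idx, fix_anchor, k_fix, forces):
    """Terminal harmonic restraints: YZ-plane, weak X, and full positional."""
    e = 0.0
    for a in range(plane_idx.shape[0]):
        i = plane_idx[a]
        for d in range(1, 3):
            dd = pos[i, d] - plane_anchor[a, d]
            e += 0.5 * k_plane * dd * dd
            forces[i, d] -= k_plane * dd
    for a in range(x_idx.shape[0]):
        i = x_idx[a]
        dd = pos[i, 0] - x_anchor[a, 0]
        e += 0.5 * k_x * dd * dd
        forces[i, 0] -= k_x * dd
    for a in range(fix_idx.shape[0]):
        i = fix_idx[a]
        for d in range(3):
            dd = pos[i, d] - fix_anchor[a, d]
            e += 0.5 * k_fix * dd * dd
            forces[i, d] -= k_fix * dd
    return e


# ---------------------------------------------------------------------------
# fused integration loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def nlist_build(pos, rep_pairs, rep_cut, skin, nb_idx, ref_pos):
    """Verlet list over the static excluded-pair list; returns active count."""
    count = 0
    for m in range(rep_pairs.shape[0]):
        i, j = rep_pairs[m, 0], rep_pairs[m, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        rc = rep_cut[m] + skin
        if r2 < rc * rc:
            nb_idx[count] = m
            count += 1
    for i in range(pos.shape[0]):
        for d in range(3):
            ref_pos[i, d] = pos[i, d]
    return count


@njit(cache=True)
def repulsion_nlist_ef(pos, rep_pairs, sig, cutoff, eps, nb_idx, nb_count, forces):
    e = 0.0
    for a in range(nb_count):
        m = nb_idx[a]
        i, j = rep_pairs[m, 0], rep_pairs[m, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        rc = cutoff[m]
        if r2 >= rc * rc:
            continue
        r = np.sqrt(r2)
        sr = sig[m] / r
        src = sig[m] / rc
        sr12 = sr ** 12
        e += eps * (sr12 - src ** 12)
        f = 12.0 * eps * sr12 / r2
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
    return e


@njit(cache=True)
def forces_full(pos, t, forces, eterms,
                bonds, bond_b0, k_bond, angles, th0, k_angle,
                omega_quads, k_omega,
                phi_quads, psi_quads, weights, eps_helix, phi0, psi0,
                sigma_basin, trans_bias, barrier3,
                hb_pairs, eps_hb, hb_d0, hb_sigma,
                rep_pairs, rep_sig, rep_cut, eps_rep, nb_idx, nb_count,
                rotate, theta, k_rot, group, ref_rel,
                plane_idx, plane_anchor, k_plane,
                x_idx, x_anchor, k_x, fix_idx, fix_anchor, k_fix):
    """Full model force evaluation; fills ``forces`` and ``eterms`` (8,).

    eterms: bond, angle, omega, torsion, hbond, repulsion, machine, torque.
    """
    for i in range(forces.shape[0]):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    eterms[0] = bond_ef(pos, bonds, bond_b0, k_bond, forces)
    eterms[1] = angle_ef(pos, angles, th0, k_angle, forces)
    eterms[2] = omega_ef(pos, omega_quads, k_omega, forces)
    eterms[3] = torsion_basin_ef(pos, phi_quads, psi_quads, weights, eps_helix,
                                 phi0, psi0, sigma_basin, trans_bias, barrier3,
                                 forces)
    eterms[4] = hbond_ef(pos, hb_pairs, eps_hb, hb_d0, hb_sigma, forces)
    eterms[5] = repulsion_nlist_ef(pos, rep_pairs, rep_sig, rep_cut, eps_rep,
                                   nb_idx, nb_count, forces)
    em = 0.0
    torque = 0.0
    if rotate:
        em, torque = rotation_ef(pos, group, ref_rel, theta, k_rot, forces)
    em += restraint_ef(pos, plane_idx, plane_anchor, k_plane,
                       x_idx, x_anchor, k_x, fix_idx, fix_anchor, k_fix, forces)
    eterms[6] = em
    eterms[7] = torque


@njit(cache=True)
def advance_chunk(pos, vel, forces, masses, dt, c1, c2, noise, t_start,
                  omega_signed_rad, work_in,
                  bonds, bond_b0, k_bond, angles, th0, k_angle,
                  omega_quads, k_omega,
                  phi_quads, psi_quads, weights, eps_helix, phi0, psi0,
                  sigma_basin, trans_bias, barrier3,
                  hb_pairs, eps_hb, hb_d0, hb_sigma,
                  rep_pairs, rep_sig, rep_cut, eps_rep,
                  nb_idx, nb_state, ref_pos, skin,
                  rotate, k_rot, group, ref_rel,
                  plane_idx, plane_anchor, k_plane,
                  x_idx, x_anchor, k_x, fix_idx, fix_anchor, k_fix,
                  eterms):
    """Integrate ``noise.shape[0]`` BAOAB steps; returns (t, work, bad_atom).

    ``bad_atom`` is -1 on success, otherwise the first atom with a
    non-finite force.  The scheme and draw order match ``langevin_step``
    exactly; ``forces`` must hold the forces at (pos, t_start) on entry
    and holds the final forces on exit.  The repulsion neighbour list in
    ``nb_idx`` / ``nb_state`` is rebuilt whenever any atom moved more than
    skin/2 since the last build.
    """
    n_steps = noise.shape[0]
    n = pos.shape[0]
    half = 0.5 * dt
    t = t_start
    work = work_in
    for s in range(n_steps):
        for i in range(n):
            im = 1.0 / masses[i]
            for d in range(3):
                vel[i, d] += half * forces[i, d] * im
                pos[i, d] += half * vel[i, d]
                vel[i, d] = c1 * vel[i, d] + c2[i] * noise[s, i, d]
                pos[i, d] += half * vel[i, d]
        t += dt
        # neighbour-list validity: max displacement since last build
        maxd2 = 0.0
        for i in range(n):
            dd = 0.0
            for d in range(3):
                diff = pos[i, d] - ref_pos[i, d]
                dd += diff * diff
            if dd > maxd2:
                maxd2 = dd
        if maxd2 > 0.25 * skin * skin:
            nb_state[0] = nlist_build(pos, rep_pairs, rep_cut, skin, nb_idx,
                                      ref_pos)
        theta = omega_signed_rad * t
        forces_full(pos, t, forces, eterms,
                    bonds, bond_b0, k_bond, angles, th0, k_angle,
                    omega_quads, k_omega,
                    phi_quads, psi_quads, weights, eps_helix, phi0, psi0,
                    sigma_basin, trans_bias, barrier3,
                    hb_pairs, eps_hb, hb_d0, hb_sigma,
                    rep_pairs, rep_sig, rep_cut, eps_rep, nb_idx, nb_state[0],
                    rotate, theta, k_rot, group, ref_rel,
                    plane_idx, plane_anchor, k_plane,
                    x_idx, x_anchor, k_x, fix_idx, fix_anchor, k_fix)
        for i in range(n):
            im = 1.0 / masses[i]
            for d in range(3):
                if not np.isfinite(forces[i, d]):
                    return t, work, i
                vel[i, d] += half * forces[i, d] * im
        if rotate:
            work += eterms[7] * omega_signed_rad * dt
    return t, work, -1
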