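"""Numba-compiled numerical kernels.

Everything in this module operates on plain numpy arrays so the hot
Monte Carlo loops stay allocation-free.  The public, documented surface
lives in :mod:`pepscreen.chain`, :mod:`pepscreen.energy` and
:mod:`pepscreen.mcmc`; those modules pack their objects into arrays and
call in here.

Atom layout: every residue owns a fixed stride of ``ATOMS_PER_RES = 6``
slots ``[N, CA, C, S1, S2, S3]``; the number of side-chain pseudo-atom
slots actually used is ``side_counts[type]`` (0..3).  Unused slots are
pinned to the residue CA position so all coordinates stay defined.

Geometry parameter vector ``geom`` (radians / Angstrom):
``[b_n_ca, b_ca_c, b_c_n, b_ca_cb, b_side,
a_n_ca_c, a_ca_c_n, a_c_n_ca, a_n_ca_cb, a_side, dih_cb, omega]``.

Energy term indices in breakdown arrays:
``0 excluded volume, 1 local torsional, 2 backbone H-bond,
3 side-chain contact, 4 desolvation, 5 receptor restraint,
6 pocket constraint``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ATOMS_PER_RES = 6
N_TERMS = 7
N_MOVES = 6  # pivot, rotamer, rigid-rot, rigid-trans, mutation, receptor

_F = "float64"


@njit(cache=True, inline="always")
def _place_atom(coords, ia, ib, ic, bond, theta, chi, iout):
    """NeRF placement: write atom ``iout`` with |c-d| = bond,
    angle(b,c,d) = theta and dihedral(a,b,c,d) = chi (IUPAC sign
    convention); a, b, c, out are row indices into ``coords``."""
    bx = coords[ic, 0] - coords[ib, 0]
    by = coords[ic, 1] - coords[ib, 1]
    bz = coords[ic, 2] - coords[ib, 2]
    bn = np.sqrt(bx * bx + by * by + bz * bz)
    bx /= bn
    by /= bn
    bz /= bn
    ax = coords[ib, 0] - coords[ia, 0]
    ay = coords[ib, 1] - coords[ia, 1]
    az = coords[ib, 2] - coords[ia, 2]
    n0 = ay * bz - az * by
    n1 = az * bx - ax * bz
    n2 = ax * by - ay * bx
    nn = np.sqrt(n0 * n0 + n1 * n1 + n2 * n2)
    n0 /= nn
    n1 /= nn
    n2 /= nn
    # m = n x bc
    m0 = n1 * bz - n2 * by
    m1 = n2 * bx - n0 * bz
    m2 = n0 * by - n1 * bx
    d0 = -bond * np.cos(theta)
    d1 = bond * np.sin(theta) * np.cos(chi)
    d2 = -bond * np.sin(theta) * np.sin(chi)
    coords[iout, 0] = coords[ic, 0] + bx * d0 + m0 * d1 + n0 * d2
    coords[iout, 1] = coords[ic, 1] + by * d0 + m1 * d1 + n1 * d2
    coords[iout, 2] = coords[ic, 2] + bz * d0 + m2 * d1 + n2 * d2


@njit(cache=True)
def build_chain(types, side_counts, phi, psi, chi, geom, rot, trans, coords):
    """Rebuild Cartesian coordinates from internal coordinates + pose.

    ``coords`` has shape (n_res * ATOMS_PER_RES, 3) and is overwritten.
    """
    n = types.shape[0]
    b_n_ca, b_ca_c, b_c_n, b_ca_cb, b_side = geom[0], geom[1], geom[2], geom[3], geom[4]
    a_n_ca_c, a_ca_c_n, a_c_n_ca = geom[5], geom[6], geom[7]
    a_n_ca_cb, a_side, dih_cb, omega = geom[8], geom[9], geom[10], geom[11]

    # build in the chain-local frame directly inside ``coords``
    coords[0, 0] = 0.0
    coords[0, 1] = 0.0
    coords[0, 2] = 0.0
    coords[1, 0] = b_n_ca
    coords[1, 1] = 0.0
    coords[1, 2] = 0.0
    coords[2, 0] = b_n_ca + b_ca_c * np.cos(np.pi - a_n_ca_c)
    coords[2, 1] = b_ca_c * np.sin(np.pi - a_n_ca_c)
    coords[2, 2] = 0.0
    for i in range(1, n):
        o = i * ATOMS_PER_RES
        p = (i - 1) * ATOMS_PER_RES
        _place_atom(coords, p + 0, p + 1, p + 2, b_c_n, a_ca_c_n, psi[i - 1], o + 0)
        _place_atom(coords, p + 1, p + 2, o + 0, b_n_ca, a_c_n_ca, omega, o + 1)
        _place_atom(coords, p + 2, o + 0, o + 1, b_ca_c, a_n_ca_c, phi[i], o + 2)
    for i in range(n):
        o = i * ATOMS_PER_RES
        k = side_counts[types[i]]
        if k >= 1:
            _place_atom(coords, o + 2, o + 0, o + 1, b_ca_cb, a_n_ca_cb,
                        dih_cb, o + 3)
        else:
            coords[o + 3] = coords[o + 1]
        if k >= 2:
            _place_atom(coords, o + 0, o + 1, o + 3, b_side, a_side,
                        chi[i, 0], o + 4)
        else:
            coords[o + 4] = coords[o + 1]
        if k >= 3:
            _place_atom(coords, o + 1, o + 3, o + 4, b_side, a_side,
                        chi[i, 1], o + 5)
        else:
            coords[o + 5] = coords[o + 1]
    for j in range(n * ATOMS_PER_RES):
        x = coords[j, 0]
        y = coords[j, 1]
        z = coords[j, 2]
        coords[j, 0] = rot[0, 0] * x + rot[0, 1] * y + rot[0, 2] * z + trans[0]
        coords[j, 1] = rot[1, 0] * x + rot[1, 1] * y + rot[1, 2] * z + trans[1]
        coords[j, 2] = rot[2, 0] * x + rot[2, 1] * y + rot[2, 2] * z + trans[2]


@njit(cache=True, inline="always")
def _min_image_1d(d, L):
    if d >= 0.5 * L:
        d -= L * np.floor(d / L + 0.5)
    elif d < -0.5 * L:
        d -= L * np.floor(d / L + 0.5)
    if d >= 0.5 * L:  # exact boundary
        d -= L
    return d


@njit(cache=True, inline="always")
def _dist2_pbc(ax, ay, az, bx, by, bz, L, periodic):
    dx = ax - bx
    dy = ay - by
    dz = az - bz
    if periodic:
        dx = _min_image_1d(dx, L)
        dy = _min_image_1d(dy, L)
        dz = _min_image_1d(dz, L)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, inline="always")
def _contact_weight(r, r_on, r_off):
    if r <= r_on:
        return 1.0
    if r >= r_off:
        return 0.0
    return (r_off - r) / (r_off - r_on)


@njit(cache=True, inline="always")
def _hbond_window(r):
    # plateau 3.2..4.6 A with linear shoulders
    if r <= 2.6 or r >= 5.4:
        return 0.0
    if r < 3.2:
        return (r - 2.6) / 0.6
    if r <= 4.6:
        return 1.0
    return (5.4 - r) / 0.8


@njit(cache=True)
def chain_energy(coords, types, side_counts, phi, psi, chi,
                 rec_xyz, rec_class, rec_strength, rec_radius, rec_nat,
                 cls_of_type, contact_mat, params, nat_anchor, L, periodic,
                 terms):
    """Total energy of the reduced model; fills the 7-entry ``terms`` array.

    ``params`` layout:
    [eps_ev, w_tor, w_chi, eps_hb, w_solv, k_restraint, k_constraint, d0,
     rad_bb, rad_side, r_on, r_off, constraint_active]
    """
    eps_ev = params[0]
    w_tor = params[1]
    w_chi = params[2]
    eps_hb = params[3]
    w_solv = params[4]
    k_restraint = params[5]
    k_constraint = params[6]
    d0 = params[7]
    rad_bb = params[8]
    rad_side = params[9]
    r_on = params[10]
    r_off = params[11]
    constraint_active = params[12] > 0.5

    n = types.shape[0]
    for q in range(N_TERMS):
        terms[q] = 0.0

    # --- excluded volume (intra-peptide, residue separation >= 2) ---
    e_ev = 0.0
    for i in range(n):
        oi = i * ATOMS_PER_RES
        ki = 3 + side_counts[types[i]]
        for j in range(i + 2, n):
            oj = j * ATOMS_PER_RES
            kj = 3 + side_counts[types[j]]
            for ai in range(ki):
                ri = rad_bb if ai < 3 else rad_side
                for aj in range(kj):
                    rj = rad_bb if aj < 3 else rad_side
                    sig = ri + rj
                    d2 = _dist2_pbc(coords[oi + ai, 0], coords[oi + ai, 1],
                                    coords[oi + ai, 2], coords[oj + aj, 0],
                                    coords[oj + aj, 1], coords[oj + aj, 2],
                                    L, False)
                    if d2 < sig * sig:
                        r = np.sqrt(d2)
                        e_ev += eps_ev * (1.0 - r / sig) ** 2
    # peptide-receptor excluded volume
    n_sites = rec_xyz.shape[0]
    for i in range(n):
        oi = i * ATOMS_PER_RES
        ki = 3 + side_counts[types[i]]
        for ai in range(ki):
            ri = rad_bb if ai < 3 else rad_side
            for s in range(n_sites):
                sig = ri + rec_radius[s]
                d2 = _dist2_pbc(coords[oi + ai, 0], coords[oi + ai, 1],
                                coords[oi + ai, 2], rec_xyz[s, 0],
                                rec_xyz[s, 1], rec_xyz[s, 2], L, periodic)
                if d2 < sig * sig:
                    r = np.sqrt(d2)
                    e_ev += eps_ev * (1.0 - r / sig) ** 2
    terms[0] = e_ev

    # --- local torsional ---
    e_loc = 0.0
    for i in range(n):
        if i > 0:
            e_loc += w_tor * (1.0 + np.cos(3.0 * phi[i]))
        if i < n - 1:
            e_loc += w_tor * (1.0 + np.cos(3.0 * psi[i]))
        m = side_counts[types[i]] - 1
        for j in range(m):
            e_loc += w_chi * (1.0 + np.cos(3.0 * chi[i, j]))
    terms[1] = e_loc

    # --- backbone hydrogen bonding ---
    # intra-peptide: donor N_i .. acceptor C_j with |i-j| >= 3;
    # peptide-receptor: backbone N/C against polar/amide sites (the
    # pocket's backbone-anchoring groups), scaled by site strength.
    e_hb = 0.0
    for i in range(n):
        for j in range(n):
            if i - j >= 3 or j - i >= 3:
                d2 = _dist2_pbc(coords[i * ATOMS_PER_RES, 0],
                                coords[i * ATOMS_PER_RES, 1],
                                coords[i * ATOMS_PER_RES, 2],
                                coords[j * ATOMS_PER_RES + 2, 0],
                                coords[j * ATOMS_PER_RES + 2, 1],
                                coords[j * ATOMS_PER_RES + 2, 2], L, False)
                if d2 < 29.16:  # 5.4^2
                    e_hb -= eps_hb * _hbond_window(np.sqrt(d2))
    for i in range(n):
        o = i * ATOMS_PER_RES
        for ai in range(0, 3, 2):
            for s in range(n_sites):
                if rec_class[s] == 1 or rec_class[s] == 2:
                    d2 = _dist2_pbc(coords[o + ai, 0], coords[o + ai, 1],
                                    coords[o + ai, 2], rec_xyz[s, 0],
                                    rec_xyz[s, 1], rec_xyz[s, 2], L, periodic)
                    if d2 < 29.16:
                        e_hb -= (eps_hb * rec_strength[s]
                                 * _hbond_window(np.sqrt(d2)))
    terms[2] = e_hb

    # --- side-chain contact energies (outermost pseudo-atom) ---
    e_sc = 0.0
    for i in range(n):
        ki = side_counts[types[i]]
        if ki == 0:
            continue
        oi = i * ATOMS_PER_RES + 2 + ki
        ci = cls_of_type[types[i]]
        for j in range(i + 2, n):
            kj = side_counts[types[j]]
            if kj == 0:
                continue
            oj = j * ATOMS_PER_RES + 2 + kj
            cj = cls_of_type[types[j]]
            d2 = _dist2_pbc(coords[oi, 0], coords[oi, 1], coords[oi, 2],
                            coords[oj, 0], coords[oj, 1], coords[oj, 2],
                            L, False)
            if d2 < r_off * r_off:
                e_sc += contact_mat[ci, cj] * _contact_weight(np.sqrt(d2), r_on, r_off)
        for s in range(n_sites):
            d2 = _dist2_pbc(coords[oi, 0], coords[oi, 1], coords[oi, 2],
                            rec_xyz[s, 0], rec_xyz[s, 1], rec_xyz[s, 2],
                            L, periodic)
            if d2 < r_off * r_off:
                e_sc += (rec_strength[s] * contact_mat[ci, rec_class[s]]
                         * _contact_weight(np.sqrt(d2), r_on, r_off))
    terms[3] = e_sc

    # --- backbone desolvation: burial of N and C sites against the bare
    # steric surface of the receptor (strength-0 sites); interaction
    # sites represent solvated functional groups and carry no burial
    # penalty ---
    e_solv = 0.0
    if n_sites > 0 and w_solv != 0.0:
        for i in range(n):
            o = i * ATOMS_PER_RES
            for ai in (0, 2):
                for s in range(n_sites):
                    if rec_strength[s] > 0.0:
                        continue
                    d2 = _dist2_pbc(coords[o + ai, 0], coords[o + ai, 1],
                                    coords[o + ai, 2], rec_xyz[s, 0],
                                    rec_xyz[s, 1], rec_xyz[s, 2], L, periodic)
                    if d2 < 30.25:  # 5.5^2
                        e_solv += w_solv * _contact_weight(np.sqrt(d2), 4.0, 5.5)
    terms[4] = e_solv

    # --- harmonic restraint of receptor sites to native positions ---
    e_res = 0.0
    if n_sites > 0 and k_restraint > 0.0:
        for s in range(n_sites):
            dx = rec_xyz[s, 0] - rec_nat[s, 0]
            dy = rec_xyz[s, 1] - rec_nat[s, 1]
            dz = rec_xyz[s, 2] - rec_nat[s, 2]
            e_res += k_restraint * (dx * dx + dy * dy + dz * dz)
    terms[5] = e_res

    # --- piecewise-linear pocket constraint on the C-terminal CA ---
    e_con = 0.0
    if constraint_active and k_constraint > 0.0:
        o = (n - 1) * ATOMS_PER_RES + 1
        d2 = _dist2_pbc(coords[o, 0], coords[o, 1], coords[o, 2],
                        nat_anchor[0], nat_anchor[1], nat_anchor[2],
                        L, periodic)
        d = np.sqrt(d2)
        if d > d0:
            e_con = k_constraint * (d - d0)
    terms[6] = e_con

    return e_ev + e_loc + e_hb + e_sc + e_solv + e_res + e_con


@njit(cache=True)
def rmsd_to_native(coords, nat_ca, L, periodic):
    """Cα RMSD to the native peptide coordinates, no superposition."""
    n = nat_ca.shape[0]
    acc = 0.0
    for i in range(n):
        o = i * ATOMS_PER_RES + 1
        acc += _dist2_pbc(coords[o, 0], coords[o, 1], coords[o, 2],
                          nat_ca[i, 0], nat_ca[i, 1], nat_ca[i, 2],
                          L, periodic)
    return np.sqrt(acc / n)


@njit(cache=True, inline="always")
def _wrap_angle(x):
    # wrap to (-pi, pi]
    y = x - 2.0 * np.pi * np.floor((x + np.pi) / (2.0 * np.pi))
    if y <= -np.pi:
        y += 2.0 * np.pi
    return y


@njit(cache=True)
def _random_rotation(amp):
    """Small random rotation matrix: random axis, uniform angle in [-amp, amp]."""
    while True:
        ux = 2.0 * np.random.random() - 1.0
        uy = 2.0 * np.random.random() - 1.0
        uz = 2.0 * np.random.random() - 1.0
        n2 = ux * ux + uy * uy + uz * uz
        if 1e-8 < n2 <= 1.0:
            break
    nn = np.sqrt(n2)
    ux /= nn
    uy /= nn
    uz /= nn
    ang = (2.0 * np.random.random() - 1.0) * amp
    c = np.cos(ang)
    s = np.sin(ang)
    C = 1.0 - c
    Q = np.empty((3, 3))
    Q[0, 0] = c + ux * ux * C
    Q[0, 1] = ux * uy * C - uz * s
    Q[0, 2] = ux * uz * C + uy * s
    Q[1, 0] = uy * ux * C + uz * s
    Q[1, 1] = c + uy * uy * C
    Q[1, 2] = uy * uz * C - ux * s
    Q[2, 0] = uz * ux * C - uy * s
    Q[2, 1] = uz * uy * C + ux * s
    Q[2, 2] = c + uz * uz * C
    return Q


@njit(cache=True)
def run_chain(types, variable_positions, side_counts, cls_of_type, geom,
              phi, psi, chi, rot, trans,
              rec_xyz, rec_class, rec_strength, rec_radius, rec_nat,
              contact_mat, params, nat_ca, nat_anchor, has_native,
              L, periodic, gamma, beta,
              move_cum, amps, mutate_excl_current,
              n_steps, burn_in, record_interval, record_angles, seed,
              rmsd_cutoff, n_rmsd_bins):
    """Joint Metropolis sampler over (conformation, sequence) of one peptide.

    Returns a tuple of accumulated statistics and trajectory records; see
    :func:`pepscreen.mcmc.run` for the object-level wrapper.
    """
    np.random.seed(seed)
    n = types.shape[0]
    n_var = variable_positions.shape[0]
    n_atoms = n * ATOMS_PER_RES

    coords = np.empty((n_atoms, 3))
    coords_p = np.empty((n_atoms, 3))
    terms = np.empty(N_TERMS)
    build_chain(types, side_counts, phi, psi, chi, geom, rot, trans, coords)
    e_cur = chain_energy(coords, types, side_counts, phi, psi, chi,
                         rec_xyz, rec_class, rec_strength, rec_radius, rec_nat,
                         cls_of_type, contact_mat, params, nat_anchor,
                         L, periodic, terms)

    # sequence index bookkeeping (only when the space is small enough)
    track_seq = n_var <= 3
    n_seq = 1
    if track_seq:
        for _ in range(n_var):
            n_seq *= 20
    seq_counts_bound = np.zeros(n_seq, dtype=np.int64)
    seq_counts_unbound = np.zeros(n_seq, dtype=np.int64)
    pos_counts = np.zeros((n_var, 20), dtype=np.int64)
    bound_pos_counts = np.zeros((n_var, 20), dtype=np.int64)
    unbound_pos_counts = np.zeros((n_var, 20), dtype=np.int64)
    rmsd_bin_counts = np.zeros((n_rmsd_bins, n_var, 20), dtype=np.int64)
    n_bound = 0
    n_counted = 0

    n_rec = n_steps // record_interval
    rec_energy = np.empty(n_rec)
    rec_rmsd = np.empty(n_rec)
    rec_bound = np.zeros(n_rec, dtype=np.int8)
    rec_seq = np.empty((n_rec, max(n_var, 1)), dtype=np.int8)
    n_ang = n if record_angles else 0
    rec_phi = np.empty((n_rec, n_ang))
    rec_psi = np.empty((n_rec, n_ang))
    rec_chi = np.empty((n_rec, n_ang, 5))

    acc = np.zeros(N_MOVES, dtype=np.int64)
    att = np.zeros(N_MOVES, dtype=np.int64)

    n_sites = rec_xyz.shape[0]
    i_rec = 0
    old_site = np.empty(3)
    for step in range(n_steps):
        u = np.random.random()
        kind = 0
        while kind < N_MOVES - 1 and u >= move_cum[kind]:
            kind += 1

        dg = 0.0
        rebuild = True
        # stash for revert
        old_a = 0.0
        idx_i = 0
        idx_j = 0
        old_type = 0
        old_rot = rot
        old_trans_x = trans[0]
        old_trans_y = trans[1]
        old_trans_z = trans[2]

        if kind == 0:  # pivot: one backbone torsion
            idx_i = np.random.randint(0, n)
            idx_j = np.random.randint(0, 2)  # 0 = phi, 1 = psi
            if idx_j == 0:
                old_a = phi[idx_i]
                phi[idx_i] = _wrap_angle(old_a + (2.0 * np.random.random() - 1.0) * amps[0])
            else:
                old_a = psi[idx_i]
                psi[idx_i] = _wrap_angle(old_a + (2.0 * np.random.random() - 1.0) * amps[0])
        elif kind == 1:  # rotamer: one formal chi (phantoms included)
            idx_i = np.random.randint(0, n)
            idx_j = np.random.randint(0, 5)
            old_a = chi[idx_i, idx_j]
            chi[idx_i, idx_j] = _wrap_angle(old_a + (2.0 * np.random.random() - 1.0) * amps[1])
        elif kind == 2:  # rigid rotation about peptide CA centroid
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for i in range(n):
                o = i * ATOMS_PER_RES + 1
                cx += coords[o, 0]
                cy += coords[o, 1]
                cz += coords[o, 2]
            cx /= n
            cy /= n
            cz /= n
            Q = _random_rotation(amps[2])
            old_rot = rot.copy()
            rot = Q @ rot
            tx = trans[0] - cx
            ty = trans[1] - cy
            tz = trans[2] - cz
            trans[0] = Q[0, 0] * tx + Q[0, 1] * ty + Q[0, 2] * tz + cx
            trans[1] = Q[1, 0] * tx + Q[1, 1] * ty + Q[1, 2] * tz + cy
            trans[2] = Q[2, 0] * tx + Q[2, 1] * ty + Q[2, 2] * tz + cz
        elif kind == 3:  # rigid translation
            trans[0] += (2.0 * np.random.random() - 1.0) * amps[3]
            trans[1] += (2.0 * np.random.random() - 1.0) * amps[3]
            trans[2] += (2.0 * np.random.random() - 1.0) * amps[3]
        elif kind == 4:  # mutation at a variable position
            v = np.random.randint(0, n_var)
            idx_i = variable_positions[v]
            old_type = types[idx_i]
            if mutate_excl_current:
                new_t = np.random.randint(0, 19)
                if new_t >= old_type:
                    new_t += 1
            else:
                new_t = np.random.randint(0, 20)
            types[idx_i] = new_t
            dg = gamma[new_t] - gamma[old_type]
        else:  # receptor site jiggle
            rebuild = False
            if n_sites > 0:
                idx_i = np.random.randint(0, n_sites)
                old_site[0] = rec_xyz[idx_i, 0]
                old_site[1] = rec_xyz[idx_i, 1]
                old_site[2] = rec_xyz[idx_i, 2]
                rec_xyz[idx_i, 0] += np.random.normal() * amps[4]
                rec_xyz[idx_i, 1] += np.random.normal() * amps[4]
                rec_xyz[idx_i, 2] += np.random.normal() * amps[4]

        if rebuild:
            build_chain(types, side_counts, phi, psi, chi, geom, rot, trans, coords_p)
            e_new = chain_energy(coords_p, types, side_counts, phi, psi, chi,
                                 rec_xyz, rec_class, rec_strength, rec_radius,
                                 rec_nat, cls_of_type, contact_mat, params,
                                 nat_anchor, L, periodic, terms)
        else:
            e_new = chain_energy(coords, types, side_counts, phi, psi, chi,
                                 rec_xyz, rec_class, rec_strength, rec_radius,
                                 rec_nat, cls_of_type, contact_mat, params,
                                 nat_anchor, L, periodic, terms)

        arg = -beta * (e_new - e_cur) + dg
        if arg >= 0.0:
            w = 1.0
        else:
            w = np.exp(arg)
        att[kind] += 1
        if np.random.random() < w:
            acc[kind] += 1
            e_cur = e_new
            if rebuild:
                tmp = coords
                coords = coords_p
                coords_p = tmp
        else:  # revert
            if kind == 0:
                if idx_j == 0:
                    phi[idx_i] = old_a
                else:
                    psi[idx_i] = old_a
            elif kind == 1:
                chi[idx_i, idx_j] = old_a
            elif kind == 2:
                rot = old_rot
                trans[0] = old_trans_x
                trans[1] = old_trans_y
                trans[2] = old_trans_z
            elif kind == 3:
                trans[0] = old_trans_x
                trans[1] = old_trans_y
                trans[2] = old_trans_z
            elif kind == 4:
                types[idx_i] = old_type
            else:
                if n_sites > 0:
                    rec_xyz[idx_i, 0] = old_site[0]
                    rec_xyz[idx_i, 1] = old_site[1]
                    rec_xyz[idx_i, 2] = old_site[2]

        if has_native:
            r = rmsd_to_native(coords, nat_ca, L, periodic)
        else:
            r = 1e30
        bound = r < rmsd_cutoff

        if step >= burn_in:
            n_counted += 1
            if bound:
                n_bound += 1
            si = 0
            for v in range(n_var):
                t = types[variable_positions[v]]
                pos_counts[v, t] += 1
                if bound:
                    bound_pos_counts[v, t] += 1
                else:
                    unbound_pos_counts[v, t] += 1
                if has_native:
                    bi = int(r)
                    if bi >= n_rmsd_bins:
                        bi = n_rmsd_bins - 1
                    rmsd_bin_counts[bi, v, t] += 1
                if track_seq:
                    si = si * 20 + t
            if track_seq and n_var > 0:
                if bound:
                    seq_counts_bound[si] += 1
                else:
                    seq_counts_unbound[si] += 1

        if (step + 1) % record_interval == 0 and i_rec < n_rec:
            rec_energy[i_rec] = e_cur
            rec_rmsd[i_rec] = r if has_native else np.nan
            rec_bound[i_rec] = 1 if bound else 0
            for v in range(n_var):
                rec_seq[i_rec, v] = types[variable_positions[v]]
            if record_angles:
                for i in range(n):
                    rec_phi[i_rec, i] = phi[i]
                    rec_psi[i_rec, i] = psi[i]
                    for j in range(5):
                        rec_chi[i_rec, i, j] = chi[i, j]
            i_rec += 1

    return (pos_counts, bound_pos_counts, unbound_pos_counts,
            seq_counts_bound, seq_counts_unbound, rmsd_bin_counts,
            n_bound, n_counted, acc, att,
            rec_energy, rec_rmsd, rec_bound, rec_seq,
            rec_phi, rec_psi, rec_chi,
            phi, psi, chi, rot, trans, rec_xyz, types, e_cur)


@njit(cache=True)
def run_toy(e_state, u_table, allowed, gamma, beta, p_conf,
            init_state, init_seq, n_steps, burn_in, seed,
            mutate_excl_current):
    """Joint Metropolis sampler on the enumerable toy catalogue.

    ``u_table`` has shape (n_states, n_var, n_alpha); energy of (c, s) is
    ``e_state[c] + sum_i u_table[c, i, s_i]``.  ``allowed`` masks the states
    the conformational proposal may visit (restriction to B or U subsets).
    Returns joint visit counts over (state, sequence-index) plus acceptance
    counters, with sequences indexed in base ``n_alpha``.
    """
    np.random.seed(seed)
    n_states, n_var, n_alpha = u_table.shape
    allowed_idx = np.empty(n_states, dtype=np.int64)
    n_allowed = 0
    for c in range(n_states):
        if allowed[c]:
            allowed_idx[n_allowed] = c
            n_allowed += 1

    n_seq = 1
    for _ in range(n_var):
        n_seq *= n_alpha

    seq = init_seq.copy()
    state = init_state

    def _energy(c, s):
        e = e_state[c]
        for i in range(n_var):
            e += u_table[c, i, s[i]]
        return e

    e_cur = _energy(state, seq)
    counts = np.zeros((n_states, n_seq), dtype=np.int64)
    acc = np.zeros(2, dtype=np.int64)
    att = np.zeros(2, dtype=np.int64)

    for step in range(n_steps):
        if np.random.random() < p_conf:
            kind = 0
            c_new = allowed_idx[np.random.randint(0, n_allowed)]
            e_new = _energy(c_new, seq)
            dg = 0.0
        else:
            kind = 1
            pos = np.random.randint(0, n_var)
            old_t = seq[pos]
            if mutate_excl_current:
                new_t = np.random.randint(0, n_alpha - 1)
                if new_t >= old_t:
                    new_t += 1
            else:
                new_t = np.random.randint(0, n_alpha)
            seq[pos] = new_t
            c_new = state
            e_new = _energy(state, seq)
            dg = gamma[new_t] - gamma[old_t]

        arg = -beta * (e_new - e_cur) + dg
        w = 1.0 if arg >= 0.0 else np.exp(arg)
        att[kind] += 1
        if np.random.random() < w:
            acc[kind] += 1
            state = c_new
            e_cur = e_new
        else:
            if kind == 1:
                seq[pos] = old_t

        if step >= burn_in:
            si = 0
            for i in range(n_var):
                si = si * n_alpha + seq[i]
            counts[state, si] += 1

    return counts, acc, att, state, seq
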