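"""Numba-compiled inner loops for the annealing engine.

The chain's backbone atoms are flattened into one (n_atoms, 3) array,
ordered N, CA, C, CB per residue.  A torsion move about phi_k or psi_k
then rotates a *contiguous suffix* of that array (everything C-terminal
of the rotated bond), so a proposal is a single Rodrigues rotation of a
block plus a cross-block energy delta; intra-block and intra-prefix
distances are unchanged by the rigid rotation and never recomputed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["anneal_kernel", "total_energy_kernel"]


@njit(cache=True, nogil=True)
def _clash_pair(r2, r_min, k_clash):
    if r2 < r_min * r_min:
        dr = r_min - np.sqrt(r2)
        return k_clash * dr * dr
    return 0.0


@njit(cache=True, nogil=True)
def _dist(pos, a, b):
    dx = pos[a, 0] - pos[b, 0]
    dy = pos[a, 1] - pos[b, 1]
    dz = pos[a, 2] - pos[b, 2]
    return np.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True, nogil=True)
def _restraint_term(d, lam, D, d0):
    if d <= d0:
        return 0.0
    viol = d - d0
    return lam * viol * viol + D * D * (1.0 - lam * lam)


@njit(cache=True, nogil=True)
def total_energy_kernel(pos, atom_res, ci, cj, lam, D, d0, r_min, k_clash):
    """Full clash + restraint energy of a configuration."""
    n = pos.shape[0]
    e = 0.0
    for a in range(n):
        ra = atom_res[a]
        for b in range(a + 1, n):
            if atom_res[b] - ra <= 1:
                continue
            dx = pos[a, 0] - pos[b, 0]
            dy = pos[a, 1] - pos[b, 1]
            dz = pos[a, 2] - pos[b, 2]
            e += _clash_pair(dx * dx + dy * dy + dz * dz, r_min, k_clash)
    for q in range(ci.shape[0]):
        e += _restraint_term(_dist(pos, ci[q], cj[q]), lam[q], D, d0)
    return e


@njit(cache=True, nogil=True)
def anneal_kernel(
    pos,            # (n_atoms, 3), modified in place
    atom_res,       # residue index per atom
    move_res,       # per candidate move: residue (0-based)
    move_is_phi,    # per candidate move: True for phi, False for psi
    suffix_start,   # per candidate move: first rotated atom row
    axis_a,         # per candidate move: atom row of axis origin
    axis_b,         # per candidate move: atom row of axis tip
    ci, cj,         # contact atom rows
    lam,            # (n_contacts,), modified in place
    sample_lambdas, # False => lambdas held fixed (refinement mode)
    D_sched, T_sched,
    d0, gamma, delta_noise, dt, r_min, k_clash,
    moves_per_step,
    pick, dmove, uacc,  # pre-drawn randoms, one triple per move
    lam_z,          # (n_steps, n_contacts) standard normals
    phi, psi,       # per-residue dihedrals (degrees), modified in place
    energy_trace,   # (n_steps,) out
):
    n_atoms = pos.shape[0]
    n_contacts = ci.shape[0]
    n_steps = D_sched.shape[0]
    scratch = np.empty_like(pos)
    m = 0
    n_accept = 0
    for step in range(n_steps):
        D = D_sched[step]
        T = T_sched[step]
        for _ in range(moves_per_step):
            k = pick[m]
            ang = dmove[m] * np.pi / 180.0
            u = uacc[m]
            m += 1
            s = suffix_start[k]
            if s >= n_atoms:
                continue
            ox = pos[axis_b[k], 0]
            oy = pos[axis_b[k], 1]
            oz = pos[axis_b[k], 2]
            ux = ox - pos[axis_a[k], 0]
            uy = oy - pos[axis_a[k], 1]
            uz = oz - pos[axis_a[k], 2]
            norm = np.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm
            ca_ = np.cos(ang)
            sa = np.sin(ang)
            ic = 1.0 - ca_
            r00 = ca_ + ux * ux * ic
            r01 = ux * uy * ic - uz * sa
            r02 = ux * uz * ic + uy * sa
            r10 = uy * ux * ic + uz * sa
            r11 = ca_ + uy * uy * ic
            r12 = uy * uz * ic - ux * sa
            r20 = uz * ux * ic - uy * sa
            r21 = uz * uy * ic + ux * sa
            r22 = ca_ + uz * uz * ic
            for t in range(s, n_atoms):
                vx = pos[t, 0] - ox
                vy = pos[t, 1] - oy
                vz = pos[t, 2] - oz
                scratch[t, 0] = ox + r00 * vx + r01 * vy + r02 * vz
                scratch[t, 1] = oy + r10 * vx + r11 * vy + r12 * vz
                scratch[t, 2] = oz + r20 * vx + r21 * vy + r22 * vz
            # cross-block clash delta
            de = 0.0
            for ta in range(s, n_atoms):
                ra = atom_res[ta]
                for tb in range(s):
                    if ra - atom_res[tb] <= 1:
                        continue
                    dx = pos[ta, 0] - pos[tb, 0]
                    dy = pos[ta, 1] - pos[tb, 1]
                    dz = pos[ta, 2] - pos[tb, 2]
                    de -= _clash_pair(dx * dx + dy * dy + dz * dz, r_min, k_clash)
                    dx = scratch[ta, 0] - pos[tb, 0]
                    dy = scratch[ta, 1] - pos[tb, 1]
                    dz = scratch[ta, 2] - pos[tb, 2]
                    de += _clash_pair(dx * dx + dy * dy + dz * dz, r_min, k_clash)
            # straddling restraint delta
            for q in range(n_contacts):
                ia = ci[q]
                ib = cj[q]
                a_in = ia >= s
                b_in = ib >= s
                if a_in == b_in:
                    continue
                if a_in:
                    mov, sta = ia, ib
                else:
                    mov, sta = ib, ia
                dx = pos[mov, 0] - pos[sta, 0]
                dy = pos[mov, 1] - pos[sta, 1]
                dz = pos[mov, 2] - pos[sta, 2]
                d_old = np.sqrt(dx * dx + dy * dy + dz * dz)
                dx = scratch[mov, 0] - pos[sta, 0]
                dy = scratch[mov, 1] - pos[sta, 1]
                dz = scratch[mov, 2] - pos[sta, 2]
                d_new = np.sqrt(dx * dx + dy * dy + dz * dz)
                de += _restraint_term(d_new, lam[q], D, d0) - _restraint_term(
                    d_old, lam[q], D, d0
                )
            accept = False
            if de <= 0.0:
                accept = True
            elif T > 0.0 and de / T < 700.0 and u < np.exp(-de / T):
                accept = True
            if accept:
                n_accept += 1
                for t in range(s, n_atoms):
                    pos[t, 0] = scratch[t, 0]
                    pos[t, 1] = scratch[t, 1]
                    pos[t, 2] = scratch[t, 2]
                rk = move_res[k]
                if move_is_phi[k]:
                    val = phi[rk] + dmove[m - 1]
                else:
                    val = psi[rk] + dmove[m - 1]
                val = (val + 180.0) % 360.0 - 180.0
                if val == -180.0:
                    val = 180.0
                if move_is_phi[k]:
                    phi[rk] = val
                else:
                    psi[rk] = val
        if sample_lambdas:
            noise_scale = delta_noise * np.sqrt(T * dt)
            for q in range(n_contacts):
                d = _dist(pos, ci[q], cj[q])
                if d > d0:
                    grad = (d - d0) * (d - d0) - 2.0 * D * D * lam[q]
                else:
                    grad = 0.0
                val = lam[q] - gamma * grad * dt + noise_scale * lam_z[step, q]
                if val < 0.0:
                    val = 0.0
                elif val > 1.0:
                    val = 1.0
                lam[q] = val
        energy_trace[step] = total_energy_kernel(
            pos, atom_res, ci, cj, lam, D, d0, r_min, k_clash
        )
    return n_accept
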