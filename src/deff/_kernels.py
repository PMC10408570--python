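"""JIT-compiled inner loops for rigid-body NVT Monte Carlo.

The Metropolis loop is exp-call dominated; running it through numba removes
the per-step array-dispatch overhead and makes million-step window sampling
practical on one core.  Only the common case lives here (NVT, rigid
translation/rotation moves, optional alchemical scaling); NPT volume moves,
external potentials and everything else stay on the plain-numpy path in
:mod:`deff.mc`.

Pair typing: ``ptype[i, j]`` is 0 for pairs the move loop must skip
(excluded, scaled 1-4, or same-molecule — all rigid-body invariants),
1 for plain pairs and 2 for alchemical solute-environment pairs.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _molecule_energy_kernel(
    x,
    box,
    pbc,
    eps_ij,
    rm_ij,
    qq_ij,
    ptype,
    members,
    mol_id,
    alpha,
    beta_sh,
    lam_e,
    lam_v,
    cutoff,
    r_on,
    krf,
    crf,
):
    e = 0.0
    n = x.shape[0]
    cutoff2 = cutoff * cutoff
    a_l = lam_v * alpha
    b_l = lam_v * beta_sh
    for ii in range(members.shape[0]):
        i = members[ii]
        mi = mol_id[i]
        for j in range(n):
            if mol_id[j] == mi:
                continue
            t = ptype[i, j]
            if t == 0:
                continue
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            if pbc:
                dx -= box[0] * round(dx / box[0])
                dy -= box[1] * round(dy / box[1])
                dz -= box[2] * round(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if pbc and r2 >= cutoff2:
                continue
            r = math.sqrt(r2)
            # vdW with switching taper
            eps = eps_ij[i, j]
            if eps > 0.0:
                xx = 1.0 - r / rm_ij[i, j]
                if t == 1:
                    u = (
                        eps
                        / (alpha - beta_sh)
                        * (beta_sh * math.exp(alpha * xx) - alpha * math.exp(beta_sh * xx))
                    )
                elif lam_v > 0.0:
                    u = (
                        lam_v
                        * eps
                        / (a_l - b_l)
                        * (b_l * math.exp(a_l * xx) - a_l * math.exp(b_l * xx))
                    )
                else:
                    u = 0.0
                if pbc and r > r_on:
                    tt = (r - r_on) / (cutoff - r_on)
                    u *= 1.0 - tt * tt * tt * (10.0 - 15.0 * tt + 6.0 * tt * tt)
                e += u
            # electrostatics (reaction field under PBC)
            qq = qq_ij[i, j]
            if qq != 0.0:
                if t == 2:
                    qq *= lam_e
                if pbc:
                    e += qq * (1.0 / r + krf * r2 - crf)
                else:
                    e += qq / r
    return e


@njit(cache=True)
def rigid_mc_nvt(
    x,
    box,
    pbc,
    eps_ij,
    rm_ij,
    qq_ij,
    ptype,
    mol_id,
    mol_ptr,
    mol_idx,
    real_ptr,
    real_idx,
    vs_ptr,
    vs_site,
    vs_parent,
    vs_h1,
    vs_h2,
    vs_dist,
    mol_cum,
    alpha,
    beta_sh,
    lam_e,
    lam_v,
    cutoff,
    r_on,
    krf,
    crf,
    p_trans,
    max_trans,
    max_rot,
    beta_t,
    n_steps,
    stride,
    seed,
    x_out,
    e_out,
):
    """Run ``n_steps`` rigid translation/rotation moves in place.

    Samples the running energy offset (relative to the starting
    configuration) and coordinate snapshots every ``stride`` steps into the
    preallocated ``e_out`` / ``x_out``.  Returns acceptance counters and the
    final energy offset.
    """
    np.random.seed(seed)
    n_mol = mol_ptr.shape[0] - 1
    de_total = 0.0
    acc_t = 0
    att_t = 0
    acc_r = 0
    att_r = 0
    n_out = 0
    old = np.empty((x.shape[0], 3))
    for step in range(n_steps):
        # pick a molecule (possibly biased towards the solute)
        u01 = np.random.random()
        im = 0
        for m in range(n_mol):
            if u01 <= mol_cum[m]:
                im = m
                break
        members = mol_idx[mol_ptr[im] : mol_ptr[im + 1]]
        e_old = _molecule_energy_kernel(
            x, box, pbc, eps_ij, rm_ij, qq_ij, ptype, members, mol_id,
            alpha, beta_sh, lam_e, lam_v, cutoff, r_on, krf, crf,
        )
        for k in range(members.shape[0]):
            i = members[k]
            old[i, 0] = x[i, 0]
            old[i, 1] = x[i, 1]
            old[i, 2] = x[i, 2]
        is_trans = np.random.random() < p_trans
        reals = real_idx[real_ptr[im] : real_ptr[im + 1]]
        if is_trans:
            att_t += 1
            sx = (np.random.random() * 2.0 - 1.0) * max_trans
            sy = (np.random.random() * 2.0 - 1.0) * max_trans
            sz = (np.random.random() * 2.0 - 1.0) * max_trans
            for k in range(reals.shape[0]):
                i = reals[k]
                x[i, 0] += sx
                x[i, 1] += sy
                x[i, 2] += sz
        else:
            att_r += 1
            ax = np.random.normal()
            ay = np.random.normal()
            az = np.random.normal()
            norm = math.sqrt(ax * ax + ay * ay + az * az)
            ax /= norm
            ay /= norm
            az /= norm
            theta = (np.random.random() * 2.0 - 1.0) * max_rot
            ct = math.cos(theta)
            st = math.sin(theta)
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for k in range(reals.shape[0]):
                i = reals[k]
                cx += x[i, 0]
                cy += x[i, 1]
                cz += x[i, 2]
            cx /= reals.shape[0]
            cy /= reals.shape[0]
            cz /= reals.shape[0]
            for k in range(reals.shape[0]):
                i = reals[k]
                px = x[i, 0] - cx
                py = x[i, 1] - cy
                pz = x[i, 2] - cz
                dot = ax * px + ay * py + az * pz
                # Rodrigues rotation about (ax, ay, az)
                rx = px * ct + (ay * pz - az * py) * st + ax * dot * (1.0 - ct)
                ry = py * ct + (az * px - ax * pz) * st + ay * dot * (1.0 - ct)
                rz = pz * ct + (ax * py - ay * px) * st + az * dot * (1.0 - ct)
                x[i, 0] = cx + rx
                x[i, 1] = cy + ry
                x[i, 2] = cz + rz
        # re-place this molecule's virtual sites
        for v in range(vs_ptr[im], vs_ptr[im + 1]):
            o = vs_parent[v]
            h1 = vs_h1[v]
            h2 = vs_h2[v]
            bx = x[h1, 0] + x[h2, 0] - 2.0 * x[o, 0]
            by = x[h1, 1] + x[h2, 1] - 2.0 * x[o, 1]
            bz = x[h1, 2] + x[h2, 2] - 2.0 * x[o, 2]
            bn = math.sqrt(bx * bx + by * by + bz * bz)
            s = vs_site[v]
            x[s, 0] = x[o, 0] + vs_dist[v] * bx / bn
            x[s, 1] = x[o, 1] + vs_dist[v] * by / bn
            x[s, 2] = x[o, 2] + vs_dist[v] * bz / bn
        e_new = _molecule_energy_kernel(
            x, box, pbc, eps_ij, rm_ij, qq_ij, ptype, members, mol_id,
            alpha, beta_sh, lam_e, lam_v, cutoff, r_on, krf, crf,
        )
        d_u = e_new - e_old
        if d_u <= 0.0 or np.random.random() < math.exp(-beta_t * d_u):
            de_total += d_u
            if is_trans:
                acc_t += 1
            else:
                acc_r += 1
        else:
            for k in range(members.shape[0]):
                i = members[k]
                x[i, 0] = old[i, 0]
                x[i, 1] = old[i, 1]
                x[i, 2] = old[i, 2]
        if (step + 1) % stride == 0:
            e_out[n_out] = de_total
            for i in range(x.shape[0]):
                x_out[n_out, i, 0] = x[i, 0]
                x_out[n_out, i, 1] = x[i, 1]
                x_out[n_out, i, 2] = x[i, 2]
            n_out += 1
    return acc_t, att_t, acc_r, att_r, de_total


@njit(cache=True)
def solute_cross_kernel(
    x,
    box,
    pbc,
    sol_idx,
    eps_ij,
    rm_ij,
    qq_ij,
    mol_id,
    alpha,
    beta_sh,
    lvs,
    cutoff,
    r_on,
    krf,
    crf,
):
    """Solute-environment cross terms in one pair sweep.

    Returns (vdw_by_lambda, elec_unit): the soft-core vdW energy at every
    requested lambda_vdw and the unit-coupling electrostatic energy.
    """
    n = x.shape[0]
    n_l = lvs.shape[0]
    vdw = np.zeros(n_l)
    elec = 0.0
    cutoff2 = cutoff * cutoff
    for ii in range(sol_idx.shape[0]):
        i = sol_idx[ii]
        mi = mol_id[i]
        for j in range(n):
            if mol_id[j] == mi:
                continue
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            if pbc:
                dx -= box[0] * round(dx / box[0])
                dy -= box[1] * round(dy / box[1])
                dz -= box[2] * round(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if pbc and r2 >= cutoff2:
                continue
            r = math.sqrt(r2)
            eps = eps_ij[i, j]
            if eps > 0.0:
                xx = 1.0 - r / rm_ij[i, j]
                sw = 1.0
                if pbc and r > r_on:
                    tt = (r - r_on) / (cutoff - r_on)
                    sw = 1.0 - tt * tt * tt * (10.0 - 15.0 * tt + 6.0 * tt * tt)
                for k in range(n_l):
                    lv = lvs[k]
                    if lv > 0.0:
                        a_l = lv * alpha
                        b_l = lv * beta_sh
                        u = (
                            lv
                            * eps
                            / (a_l - b_l)
                            * (b_l * math.exp(a_l * xx) - a_l * math.exp(b_l * xx))
                        )
                        vdw[k] += u * sw
            qq = qq_ij[i, j]
            if qq != 0.0:
                if pbc:
                    elec += qq * (1.0 / r + krf * r2 - crf)
                else:
                    elec += qq / r
    return vdw, elec
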