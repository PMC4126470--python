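"""Numba kernel for NPT Metropolis sweeps with linked-cell neighbour search.

One sweep = one attempted trial displacement per bead (uniform in a cube
of side 2*disp_max, Metropolis acceptance exp(-dU/T)) followed by one
trial box move per free axis (uniform step in ln L, affine coordinate
rescale, acceptance exp(-[dU + P dV - N T ln(V'/V)]/T)).

The linked cell list (head/next/prev + cell-of arrays) is kept current:
accepted displacements relink the moved bead, accepted box moves rebuild
the list, so the cell edge can be the bare interaction cutoff.  Boxes
too small for three cells on every axis fall back to an all-pairs scan.

All arrays are packed by :func:`memelast.mc._pack_system`; bond style
0 is FENE, 1 is harmonic.
"""
import numpy as np
from numba import njit

BIG = 1e30  # sentinel energy for a broken FENE bond


@njit(cache=True, fastmath=True)
def _mi(d, L):
    return d - L * np.round(d / L)


@njit(cache=True, fastmath=True)
def _pair_e(r2, eps, sig, shift):
    s2 = sig * sig / r2
    s6 = s2 * s2 * s2
    return eps * (s6 * s6 - 2.0 * s6) - shift


@njit(cache=True, fastmath=True)
def _bond_e(r, style, k, r0, drm):
    dr = r - r0
    if style == 0:
        if abs(dr) >= drm:
            return BIG
        x = dr / drm
        return -0.5 * k * drm * drm * np.log(1.0 - x * x)
    return 0.5 * k * dr * dr


@njit(cache=True)
def _cell_grid(box, edge):
    ncx = int(box[0] / edge)
    ncy = int(box[1] / edge)
    ncz = int(box[2] / edge)
    if ncx < 3 or ncy < 3 or ncz < 3:
        return 1, 1, 1, False
    return ncx, ncy, ncz, True


@njit(cache=True, fastmath=True)
def _cell_of_point(x, y, z, box, ncx, ncy, ncz):
    cx = int(((x % box[0]) / box[0]) * ncx)
    cy = int(((y % box[1]) / box[1]) * ncy)
    cz = int(((z % box[2]) / box[2]) * ncz)
    if cx >= ncx:
        cx = ncx - 1
    if cy >= ncy:
        cy = ncy - 1
    if cz >= ncz:
        cz = ncz - 1
    return (cx * ncy + cy) * ncz + cz, cx, cy, cz


@njit(cache=True)
def _build_cells(pos, box, ncx, ncy, ncz):
    n = pos.shape[0]
    head = -np.ones(ncx * ncy * ncz, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    prv = -np.ones(n, dtype=np.int64)
    cell_of = np.zeros(n, dtype=np.int64)
    for i in range(n):
        c, _, _, _ = _cell_of_point(pos[i, 0], pos[i, 1], pos[i, 2], box, ncx, ncy, ncz)
        nxt[i] = head[c]
        prv[i] = -1
        if head[c] != -1:
            prv[head[c]] = i
        head[c] = i
        cell_of[i] = c
    return head, nxt, prv, cell_of


@njit(cache=True)
def _relink(i, c_new, head, nxt, prv, cell_of):
    c_old = cell_of[i]
    if c_old == c_new:
        return
    if prv[i] == -1:
        head[c_old] = nxt[i]
    else:
        nxt[prv[i]] = nxt[i]
    if nxt[i] != -1:
        prv[nxt[i]] = prv[i]
    nxt[i] = head[c_new]
    prv[i] = -1
    if head[c_new] != -1:
        prv[head[c_new]] = i
    head[c_new] = i
    cell_of[i] = c_new


@njit(cache=True)
def _is_excluded(i, j, excl_start, excl_flat):
    for k in range(excl_start[i], excl_start[i + 1]):
        if excl_flat[k] == j:
            return True
    return False


@njit(cache=True, fastmath=True)
def _nb_energy_point(i, x, y, z, pos, kinds, box,
                     eps, sig, rc2, shift, active,
                     excl_start, excl_flat,
                     head, nxt, ncx, ncy, ncz, use_cells):
    """Non-bonded energy of a probe at (x,y,z) carrying bead i's identity."""
    e = 0.0
    ki = kinds[i]
    if use_cells:
        _, cx, cy, cz = _cell_of_point(x, y, z, box, ncx, ncy, ncz)
        for ox in range(-1, 2):
            ccx = (cx + ox) % ncx
            for oy in range(-1, 2):
                ccy = (cy + oy) % ncy
                for oz in range(-1, 2):
                    ccz = (cz + oz) % ncz
                    j = head[(ccx * ncy + ccy) * ncz + ccz]
                    while j != -1:
                        if j != i:
                            kj = kinds[j]
                            if active[ki, kj]:
                                dx = _mi(x - pos[j, 0], box[0])
                                dy = _mi(y - pos[j, 1], box[1])
                                dz = _mi(z - pos[j, 2], box[2])
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 < rc2[ki, kj]:
                                    if not _is_excluded(i, j, excl_start, excl_flat):
                                        e += _pair_e(r2, eps[ki, kj], sig[ki, kj], shift[ki, kj])
                        j = nxt[j]
    else:
        for j in range(pos.shape[0]):
            if j == i:
                continue
            kj = kinds[j]
            if not active[ki, kj]:
                continue
            dx = _mi(x - pos[j, 0], box[0])
            dy = _mi(y - pos[j, 1], box[1])
            dz = _mi(z - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2[ki, kj]:
                if not _is_excluded(i, j, excl_start, excl_flat):
                    e += _pair_e(r2, eps[ki, kj], sig[ki, kj], shift[ki, kj])
    return e


@njit(cache=True, fastmath=True)
def _angle_term(ai, aj, ak, pos, box, nu_ba):
    ux = _mi(pos[aj, 0] - pos[ai, 0], box[0])
    uy = _mi(pos[aj, 1] - pos[ai, 1], box[1])
    uz = _mi(pos[aj, 2] - pos[ai, 2], box[2])
    vx = _mi(pos[ak, 0] - pos[aj, 0], box[0])
    vy = _mi(pos[ak, 1] - pos[aj, 1], box[1])
    vz = _mi(pos[ak, 2] - pos[aj, 2], box[2])
    nu = np.sqrt(ux * ux + uy * uy + uz * uz)
    nv = np.sqrt(vx * vx + vy * vy + vz * vz)
    c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return nu_ba * (1.0 - c)


@njit(cache=True, fastmath=True)
def _bead_bonded_energy(i, pos, box,
                        bond_i, bond_j, bond_style, bond_k, bond_r0, bond_drm,
                        bead_bond_start, bead_bond_flat,
                        ang_i, ang_j, ang_k, nu_ba,
                        bead_ang_start, bead_ang_flat):
    e = 0.0
    for idx in range(bead_bond_start[i], bead_bond_start[i + 1]):
        b = bead_bond_flat[idx]
        a0 = bond_i[b]
        a1 = bond_j[b]
        dx = _mi(pos[a1, 0] - pos[a0, 0], box[0])
        dy = _mi(pos[a1, 1] - pos[a0, 1], box[1])
        dz = _mi(pos[a1, 2] - pos[a0, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        eb = _bond_e(r, bond_style[b], bond_k[b], bond_r0[b], bond_drm[b])
        if eb >= BIG:
            return BIG
        e += eb
    if nu_ba > 0.0:
        for idx in range(bead_ang_start[i], bead_ang_start[i + 1]):
            a = bead_ang_flat[idx]
            e += _angle_term(ang_i[a], ang_j[a], ang_k[a], pos, box, nu_ba)
    return e


@njit(cache=True, fastmath=True)
def total_energy_kernel(pos, kinds, box,
                        bond_i, bond_j, bond_style, bond_k, bond_r0, bond_drm,
                        ang_i, ang_j, ang_k, nu_ba,
                        eps, sig, rc2, shift, active,
                        excl_start, excl_flat, edge):
    """Full energy via cell lists (or all-pairs); BIG if a FENE bond broke."""
    n = pos.shape[0]
    e = 0.0
    for b in range(bond_i.shape[0]):
        a0 = bond_i[b]
        a1 = bond_j[b]
        dx = _mi(pos[a1, 0] - pos[a0, 0], box[0])
        dy = _mi(pos[a1, 1] - pos[a0, 1], box[1])
        dz = _mi(pos[a1, 2] - pos[a0, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        eb = _bond_e(r, bond_style[b], bond_k[b], bond_r0[b], bond_drm[b])
        if eb >= BIG:
            return BIG
        e += eb
    if nu_ba > 0.0:
        for a in range(ang_i.shape[0]):
            e += _angle_term(ang_i[a], ang_j[a], ang_k[a], pos, box, nu_ba)
    ncx, ncy, ncz, use_cells = _cell_grid(box, edge)
    if use_cells:
        head, nxt, prv, cell_of = _build_cells(pos, box, ncx, ncy, ncz)
        # half-shell iteration: own cell with j > i, plus the 13 cells in
        # the lexicographically positive half (valid for >= 3 cells/axis)
        for i in range(n):
            ki = kinds[i]
            _, cx, cy, cz = _cell_of_point(pos[i, 0], pos[i, 1], pos[i, 2],
                                           box, ncx, ncy, ncz)
            for ox in range(-1, 2):
                ccx = (cx + ox) % ncx
                for oy in range(-1, 2):
                    ccy = (cy + oy) % ncy
                    for oz in range(-1, 2):
                        own = ox == 0 and oy == 0 and oz == 0
                        forward = (ox > 0 or (ox == 0 and oy > 0)
                                   or (ox == 0 and oy == 0 and oz > 0))
                        if not (own or forward):
                            continue
                        ccz = (cz + oz) % ncz
                        j = head[(ccx * ncy + ccy) * ncz + ccz]
                        while j != -1:
                            if (not own) or j > i:
                                kj = kinds[j]
                                if active[ki, kj]:
                                    dx = _mi(pos[i, 0] - pos[j, 0], box[0])
                                    dy = _mi(pos[i, 1] - pos[j, 1], box[1])
                                    dz = _mi(pos[i, 2] - pos[j, 2], box[2])
                                    r2 = dx * dx + dy * dy + dz * dz
                                    if r2 < rc2[ki, kj]:
                                        if not _is_excluded(i, j, excl_start, excl_flat):
                                            e += _pair_e(r2, eps[ki, kj], sig[ki, kj],
                                                         shift[ki, kj])
                            j = nxt[j]
    else:
        for i in range(n):
            ki = kinds[i]
            for j in range(i + 1, n):
                kj = kinds[j]
                if not active[ki, kj]:
                    continue
                dx = _mi(pos[i, 0] - pos[j, 0], box[0])
                dy = _mi(pos[i, 1] - pos[j, 1], box[1])
                dz = _mi(pos[i, 2] - pos[j, 2], box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rc2[ki, kj]:
                    if not _is_excluded(i, j, excl_start, excl_flat):
                        e += _pair_e(r2, eps[ki, kj], sig[ki, kj], shift[ki, kj])
    return e


@njit(cache=True, fastmath=True)
def run_npt(pos, kinds, box,
            bond_i, bond_j, bond_style, bond_k, bond_r0, bond_drm,
            bead_bond_start, bead_bond_flat,
            ang_i, ang_j, ang_k, nu_ba,
            bead_ang_start, bead_ang_flat,
            eps, sig, rc2, shift, active,
            excl_start, excl_flat,
            well_k, wcx, wcy, wcz,
            T, P, disp_max, box_step,
            move_x, move_y, move_z,
            free_x, free_y, free_z,
            n_sweeps, sample_stride, seed):
    """Run ``n_sweeps`` NPT sweeps in place; returns observables and counters.

    Returns (obs, U, acc_disp, att_disp, acc_box, att_box) where obs has
    one row (Lx, Ly, Lz, U, V) every ``sample_stride`` sweeps.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    edge = 0.0
    for a in range(3):
        for b in range(3):
            if active[a, b]:
                rc = np.sqrt(rc2[a, b])
                if rc > edge:
                    edge = rc
    if edge <= 0.0:
        edge = 1.0

    n_rec = n_sweeps // sample_stride if sample_stride > 0 else 0
    obs = np.zeros((n_rec, 5))
    trial_pos = np.empty_like(pos)

    U = total_energy_kernel(pos, kinds, box,
                            bond_i, bond_j, bond_style, bond_k, bond_r0, bond_drm,
                            ang_i, ang_j, ang_k, nu_ba,
                            eps, sig, rc2, shift, active,
                            excl_start, excl_flat, edge)
    if well_k > 0.0:
        for i in range(n):
            dx = pos[i, 0] - wcx
            dy = pos[i, 1] - wcy
            dz = pos[i, 2] - wcz
            U += 0.5 * well_k * (dx * dx + dy * dy + dz * dz)

    ncx, ncy, ncz, use_cells = _cell_grid(box, edge)
    if use_cells:
        head, nxt, prv, cell_of = _build_cells(pos, box, ncx, ncy, ncz)
    else:
        head = -np.ones(1, dtype=np.int64)
        nxt = -np.ones(n, dtype=np.int64)
        prv = -np.ones(n, dtype=np.int64)
        cell_of = np.zeros(n, dtype=np.int64)

    acc_disp = 0
    att_disp = 0
    acc_box = 0
    att_box = 0
    rec = 0
    for sweep in range(n_sweeps):
        # --- single-bead displacement moves ---------------------------
        for i in range(n):
            att_disp += 1
            ox = pos[i, 0]
            oy = pos[i, 1]
            oz = pos[i, 2]
            nx_ = ox + (np.random.uniform(-1.0, 1.0) * disp_max if move_x else 0.0)
            ny_ = oy + (np.random.uniform(-1.0, 1.0) * disp_max if move_y else 0.0)
            nz_ = oz + (np.random.uniform(-1.0, 1.0) * disp_max if move_z else 0.0)
            e_old = _nb_energy_point(i, ox, oy, oz, pos, kinds, box,
                                     eps, sig, rc2, shift, active,
                                     excl_start, excl_flat,
                                     head, nxt, ncx, ncy, ncz, use_cells)
            e_old += _bead_bonded_energy(i, pos, box,
                                         bond_i, bond_j, bond_style, bond_k,
                                         bond_r0, bond_drm,
                                         bead_bond_start, bead_bond_flat,
                                         ang_i, ang_j, ang_k, nu_ba,
                                         bead_ang_start, bead_ang_flat)
            if well_k > 0.0:
                e_old += 0.5 * well_k * ((ox - wcx) ** 2 + (oy - wcy) ** 2 + (oz - wcz) ** 2)
            pos[i, 0] = nx_
            pos[i, 1] = ny_
            pos[i, 2] = nz_
            e_new = _bead_bonded_energy(i, pos, box,
                                        bond_i, bond_j, bond_style, bond_k,
                                        bond_r0, bond_drm,
                                        bead_bond_start, bead_bond_flat,
                                        ang_i, ang_j, ang_k, nu_ba,
                                        bead_ang_start, bead_ang_flat)
            if e_new < BIG:
                e_new += _nb_energy_point(i, nx_, ny_, nz_, pos, kinds, box,
                                          eps, sig, rc2, shift, active,
                                          excl_start, excl_flat,
                                          head, nxt, ncx, ncy, ncz, use_cells)
                if well_k > 0.0:
                    e_new += 0.5 * well_k * ((nx_ - wcx) ** 2 + (ny_ - wcy) ** 2 + (nz_ - wcz) ** 2)
            dU = e_new - e_old
            accept = False
            if e_new < BIG:
                if dU <= 0.0:
                    accept = True
                elif np.random.random() < np.exp(-dU / T):
                    accept = True
            if accept:
                # keep coordinates wrapped (well runs use a fixed box and
                # stay near its centre; skip wrapping to keep raw samples)
                if well_k == 0.0:
                    pos[i, 0] = nx_ % box[0]
                    pos[i, 1] = ny_ % box[1]
                    pos[i, 2] = nz_ % box[2]
                U += dU
                acc_disp += 1
                if use_cells:
                    c_new, _, _, _ = _cell_of_point(pos[i, 0], pos[i, 1], pos[i, 2],
                                                    box, ncx, ncy, ncz)
                    _relink(i, c_new, head, nxt, prv, cell_of)
            else:
                pos[i, 0] = ox
                pos[i, 1] = oy
                pos[i, 2] = oz
        # --- per-axis box moves ---------------------------------------
        for axis in range(3):
            if axis == 0 and not free_x:
                continue
            if axis == 1 and not free_y:
                continue
            if axis == 2 and not free_z:
                continue
            att_box += 1
            f = np.exp(np.random.uniform(-1.0, 1.0) * box_step)
            for i in range(n):
                trial_pos[i, 0] = pos[i, 0]
                trial_pos[i, 1] = pos[i, 1]
                trial_pos[i, 2] = pos[i, 2]
                trial_pos[i, axis] = pos[i, axis] * f
            old_L = box[axis]
            box[axis] = old_L * f
            U_new = total_energy_kernel(trial_pos, kinds, box,
                                        bond_i, bond_j, bond_style, bond_k,
                                        bond_r0, bond_drm,
                                        ang_i, ang_j, ang_k, nu_ba,
                                        eps, sig, rc2, shift, active,
                                        excl_start, excl_flat, edge)
            accept = False
            if U_new < BIG:
                V_old = box[0] * box[1] * box[2] / f
                V_new = V_old * f
                arg = -(U_new - U + P * (V_new - V_old)) / T + n * np.log(f)
                if arg >= 0.0:
                    accept = True
                elif np.random.random() < np.exp(arg):
                    accept = True
            if accept:
                for i in range(n):
                    pos[i, 0] = trial_pos[i, 0]
                    pos[i, 1] = trial_pos[i, 1]
                    pos[i, 2] = trial_pos[i, 2]
                U = U_new
                acc_box += 1
                ncx, ncy, ncz, use_cells = _cell_grid(box, edge)
                if use_cells:
                    head, nxt, prv, cell_of = _build_cells(pos, box, ncx, ncy, ncz)
            else:
                box[axis] = old_L
        # --- sampling --------------------------------------------------
        if sample_stride > 0 and (sweep + 1) % sample_stride == 0:
            obs[rec, 0] = box[0]
            obs[rec, 1] = box[1]
            obs[rec, 2] = box[2]
            obs[rec, 3] = U
            obs[rec, 4] = box[0] * box[1] * box[2]
            rec += 1
    return obs, U, acc_disp, att_disp, acc_box, att_box
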