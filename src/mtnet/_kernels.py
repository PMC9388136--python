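"""Numba kernels for force assembly, integration and linker kinetics.

The simulation state lives in flat numpy arrays (struct-of-arrays) so
the whole step loop can run inside compiled code:

* ``fverts[f, v, :]`` filament vertex positions (µm, unwrapped X/Y);
* ``lfil[l, j]`` / ``labs[l, j]`` per-unit anchor (filament index or -1,
  abscissa from the minus end);
* per-spec parameter tables indexed by ``lspec[l]``.

Periodicity enters only through minimum-image differences; Z is folded
back by mirror reflection.

Bending elasticity and the cross-link springs are integrated
*implicitly* (backward Euler): the stiffest discrete bending modes,
and the stiffness of many cross-linkers stacked between one filament
pair, sit far above the explicit stability limit at the production
time step.  Both force families are linear (springs after freezing the
unit extension direction and periodic image at the step start), so the
three coordinates satisfy independent linear systems with one shared
matrix, solved together by conjugate gradients preconditioned with the
per-filament inverse bending operator.  Steric forces, which are
one-sided and self-limiting, stay explicit.

Neighbor search uses X/Y cell grids (rebuilt every step, counting-sort
compact layout): a coarse grid for segment--segment steric pairs and a
finer one for binding-site queries.

Randomness uses numba's internal ``np.random`` state, seeded once per
run through :func:`seed_rng`; with a fixed seed and configuration the
trajectory is bitwise reproducible.
"""

import numpy as np
from numba import njit

LATTICE = 0.008  # binding-site spacing, µm

_NJIT = dict(cache=True)


@njit(**_NJIT)
def seed_rng(seed):
    np.random.seed(seed)


@njit(inline="always")
def _wrap1(x, period):
    """Map a scalar displacement to [-period/2, period/2)."""
    return x - period * np.floor(x / period + 0.5)


@njit(inline="always")
def _anchor_kt(fnv, flast, seg_rest, fil, a):
    """Abscissa -> (segment index, fraction along segment)."""
    nv = fnv[fil]
    body = (nv - 2) * seg_rest
    if a >= body:
        k = nv - 2
        lr = flast[fil]
        t = (a - body) / lr if lr > 1e-12 else 0.0
        if t > 1.0:
            t = 1.0
    else:
        k = int(a / seg_rest)
        if k > nv - 2:
            k = nv - 2
        t = a / seg_rest - k
    return k, t


@njit(**_NJIT)
def _build_cells(fverts, fnv, nf, lx, ly, cell_min):
    """Enumerate filament segments and bin them on an X/Y cell grid
    (counting sort, compact per-cell ranges).

    Returns ``(seg_fil, seg_k, order, start, ncx, ncy, use_cells)``:
    segments of cell ``c`` are ``order[start[c]:start[c+1]]``.  When
    the grid is too coarse for a correct 3x3 neighborhood (fewer than
    4 cells per axis) ``use_cells`` is False and callers fall back to
    all-pairs iteration over ``order`` (= identity).
    """
    m = 0
    for f in range(nf):
        m += fnv[f] - 1
    seg_fil = np.empty(m, np.int64)
    seg_k = np.empty(m, np.int64)
    i = 0
    for f in range(nf):
        for k in range(fnv[f] - 1):
            seg_fil[i] = f
            seg_k[i] = k
            i += 1
    ncx = max(1, int(lx / cell_min))
    ncy = max(1, int(ly / cell_min))
    use_cells = ncx >= 4 and ncy >= 4
    ncell = ncx * ncy
    start = np.zeros(ncell + 1, np.int64)
    order = np.empty(m, np.int64)
    if use_cells:
        csx = lx / ncx
        csy = ly / ncy
        cell_of = np.empty(m, np.int64)
        for s in range(m):
            f = seg_fil[s]
            k = seg_k[s]
            mx = 0.5 * (fverts[f, k, 0] + fverts[f, k + 1, 0])
            my = 0.5 * (fverts[f, k, 1] + fverts[f, k + 1, 1])
            mx -= lx * np.floor(mx / lx)
            my -= ly * np.floor(my / ly)
            cx = min(int(mx / csx), ncx - 1)
            cy = min(int(my / csy), ncy - 1)
            c = cy * ncx + cx
            cell_of[s] = c
            start[c + 1] += 1
        for c in range(ncell):
            start[c + 1] += start[c]
        fill = start[:ncell].copy()
        for s in range(m):
            c = cell_of[s]
            order[fill[c]] = s
            fill[c] += 1
    else:
        for s in range(m):
            order[s] = s
    return seg_fil, seg_k, order, start, ncx, ncy, use_cells


@njit(inline="always")
def _seg_pair_steric(fverts, seg_fil, seg_k, i, j, lx, ly,
                     k_steric, d_steric, F):
    f1 = seg_fil[i]
    f2 = seg_fil[j]
    if f1 == f2:
        return
    k1 = seg_k[i]
    k2 = seg_k[j]
    p1x = fverts[f1, k1, 0]
    p1y = fverts[f1, k1, 1]
    p1z = fverts[f1, k1, 2]
    d1x = fverts[f1, k1 + 1, 0] - p1x
    d1y = fverts[f1, k1 + 1, 1] - p1y
    d1z = fverts[f1, k1 + 1, 2] - p1z
    p2x = fverts[f2, k2, 0]
    p2y = fverts[f2, k2, 1]
    p2z = fverts[f2, k2, 2]
    d2x = fverts[f2, k2 + 1, 0] - p2x
    d2y = fverts[f2, k2 + 1, 1] - p2y
    d2z = fverts[f2, k2 + 1, 2] - p2z
    # shift segment 2 to the periodic image nearest segment 1 (midpoints)
    m1x = p1x + 0.5 * d1x
    m1y = p1y + 0.5 * d1y
    m2x = p2x + 0.5 * d2x
    m2y = p2y + 0.5 * d2y
    sx = _wrap1(m2x - m1x, lx) - (m2x - m1x)
    sy = _wrap1(m2y - m1y, ly) - (m2y - m1y)
    p2x += sx
    p2y += sy
    # closest points between the two segments (clamped parameters)
    rx = p1x - p2x
    ry = p1y - p2y
    rz = p1z - p2z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    b = d1x * d2x + d1y * d2y + d1z * d2z
    c = d1x * rx + d1y * ry + d1z * rz
    f = d2x * rx + d2y * ry + d2z * rz
    denom = a * e - b * b
    if denom > 1e-14:
        s = (b * f - c * e) / denom
        s = min(max(s, 0.0), 1.0)
    else:
        s = 0.0
    t = (b * s + f) / e if e > 1e-14 else 0.0
    if t < 0.0:
        t = 0.0
        s = min(max(-c / a, 0.0), 1.0) if a > 1e-14 else 0.0
    elif t > 1.0:
        t = 1.0
        s = min(max((b - c) / a, 0.0), 1.0) if a > 1e-14 else 0.0
    c1x = p1x + s * d1x
    c1y = p1y + s * d1y
    c1z = p1z + s * d1z
    c2x = p2x + t * d2x
    c2y = p2y + t * d2y
    c2z = p2z + t * d2z
    nx = c1x - c2x
    ny = c1y - c2y
    nz = c1z - c2z
    dist = np.sqrt(nx * nx + ny * ny + nz * nz)
    if dist >= d_steric:
        return
    if dist < 1e-9:
        # exactly coincident closest points: random in-plane direction
        th = np.random.random() * 6.283185307179586
        nx = np.cos(th)
        ny = np.sin(th)
        nz = 0.0
    else:
        nx /= dist
        ny /= dist
        nz /= dist
    # remove components along both filament axes so the repulsion is
    # perpendicular (minimal axial sliding force)
    ia = 1.0 / np.sqrt(a) if a > 1e-14 else 0.0
    ie = 1.0 / np.sqrt(e) if e > 1e-14 else 0.0
    u1x = d1x * ia
    u1y = d1y * ia
    u1z = d1z * ia
    u2x = d2x * ie
    u2y = d2y * ie
    u2z = d2z * ie
    g = u1x * u2x + u1y * u2y + u1z * u2z
    b1 = nx * u1x + ny * u1y + nz * u1z
    b2 = nx * u2x + ny * u2y + nz * u2z
    det = 1.0 - g * g
    if det > 1e-9:
        al = (b1 - g * b2) / det
        be = (b2 - g * b1) / det
        wx = nx - al * u1x - be * u2x
        wy = ny - al * u1y - be * u2y
        wz = nz - al * u1z - be * u2z
    else:  # near-parallel axes: a single projection suffices
        wx = nx - b1 * u1x
        wy = ny - b1 * u1y
        wz = nz - b1 * u1z
    wn = np.sqrt(wx * wx + wy * wy + wz * wz)
    if wn < 1e-9:
        # direction degenerate with both axes: any perpendicular to u1
        wx = u1y
        wy = -u1x
        wz = 0.0
        wn = np.sqrt(wx * wx + wy * wy)
        if wn < 1e-9:
            wx, wy, wz = 1.0, 0.0, 0.0
            wn = 1.0
    wx /= wn
    wy /= wn
    wz /= wn
    if wx * nx + wy * ny + wz * nz < 0.0:
        wx = -wx
        wy = -wy
        wz = -wz
    mag = k_steric * (d_steric - dist)
    fx = mag * wx
    fy = mag * wy
    fz = mag * wz
    F[f1, k1, 0] += (1.0 - s) * fx
    F[f1, k1, 1] += (1.0 - s) * fy
    F[f1, k1, 2] += (1.0 - s) * fz
    F[f1, k1 + 1, 0] += s * fx
    F[f1, k1 + 1, 1] += s * fy
    F[f1, k1 + 1, 2] += s * fz
    F[f2, k2, 0] -= (1.0 - t) * fx
    F[f2, k2, 1] -= (1.0 - t) * fy
    F[f2, k2, 2] -= (1.0 - t) * fz
    F[f2, k2 + 1, 0] -= t * fx
    F[f2, k2 + 1, 1] -= t * fy
    F[f2, k2 + 1, 2] -= t * fz


@njit(**_NJIT)
def compute_forces(fverts, fnv, flen, flast, nf, seg_rest, kappa,
                   include_bending, include_springs,
                   lx, ly, k_steric, d_steric, cell_min,
                   lspec, lfil, labs, s_k, s_e, u_is_motor, u_dir,
                   F, lforce, lfpar):
    """Assemble deterministic forces into ``F`` (zeroed here).

    ``include_bending`` / ``include_springs`` control whether those
    (implicitly integrated) families are written into ``F``; the
    per-linker spring force on unit 0 (``lforce``) and its projection
    on each unit's motion direction (``lfpar``) are always stored for
    the kinetic update.
    """
    F[:, :, :] = 0.0
    lforce[:, :] = 0.0
    lfpar[:, :] = 0.0

    # bending: F = -(kappa / l^3) A^T A x on each filament
    if include_bending and kappa > 0.0:
        kb = kappa / seg_rest ** 3
        for fi in range(nf):
            nv = fnv[fi]
            for j in range(1, nv - 1):
                for c in range(3):
                    sec = (fverts[fi, j + 1, c] - 2.0 * fverts[fi, j, c]
                           + fverts[fi, j - 1, c])
                    F[fi, j + 1, c] -= kb * sec
                    F[fi, j, c] += 2.0 * kb * sec
                    F[fi, j - 1, c] -= kb * sec

    # steric repulsion between nearby segments of distinct filaments
    if k_steric > 0.0 and nf > 1:
        seg_fil, seg_k, order, startc, ncx, ncy, use_cells = _build_cells(
            fverts, fnv, nf, lx, ly, cell_min)
        m = seg_fil.shape[0]
        if use_cells:
            for cy in range(ncy):
                for cx in range(ncx):
                    c0 = cy * ncx + cx
                    i0 = startc[c0]
                    i1 = startc[c0 + 1]
                    for aa in range(i0, i1):
                        i = order[aa]
                        for bb in range(aa + 1, i1):
                            _seg_pair_steric(fverts, seg_fil, seg_k, i,
                                             order[bb], lx, ly,
                                             k_steric, d_steric, F)
                        # half of the 8 neighbors: no double counting
                        for nb in range(4):
                            if nb == 0:
                                ox, oy = 1, 0
                            elif nb == 1:
                                ox, oy = 1, 1
                            elif nb == 2:
                                ox, oy = 0, 1
                            else:
                                ox, oy = -1, 1
                            c1 = ((cy + oy) % ncy) * ncx + (cx + ox) % ncx
                            for bb in range(startc[c1], startc[c1 + 1]):
                                _seg_pair_steric(fverts, seg_fil, seg_k, i,
                                                 order[bb], lx, ly,
                                                 k_steric, d_steric, F)
        else:
            for i in range(m):
                for j in range(i + 1, m):
                    _seg_pair_steric(fverts, seg_fil, seg_k, i, j,
                                     lx, ly, k_steric, d_steric, F)

    # cross-link Hookean springs, distributed to the bounding vertices
    nl = lspec.shape[0]
    for li in range(nl):
        if lfil[li, 0] < 0 or lfil[li, 1] < 0:
            continue
        sp = lspec[li]
        f0 = lfil[li, 0]
        f1 = lfil[li, 1]
        k0, t0 = _anchor_kt(fnv, flast, seg_rest, f0, labs[li, 0])
        k1, t1 = _anchor_kt(fnv, flast, seg_rest, f1, labs[li, 1])
        p0x = (1.0 - t0) * fverts[f0, k0, 0] + t0 * fverts[f0, k0 + 1, 0]
        p0y = (1.0 - t0) * fverts[f0, k0, 1] + t0 * fverts[f0, k0 + 1, 1]
        p0z = (1.0 - t0) * fverts[f0, k0, 2] + t0 * fverts[f0, k0 + 1, 2]
        p1x = (1.0 - t1) * fverts[f1, k1, 0] + t1 * fverts[f1, k1 + 1, 0]
        p1y = (1.0 - t1) * fverts[f1, k1, 1] + t1 * fverts[f1, k1 + 1, 1]
        p1z = (1.0 - t1) * fverts[f1, k1, 2] + t1 * fverts[f1, k1 + 1, 2]
        ux = _wrap1(p1x - p0x, lx)
        uy = _wrap1(p1y - p0y, ly)
        uz = p1z - p0z
        dn = np.sqrt(ux * ux + uy * uy + uz * uz)
        if dn < 1e-12:
            continue  # degenerate coincident anchors: no defined direction
        fac = s_k[sp] * (1.0 - s_e[sp] / dn)
        fx = fac * ux
        fy = fac * uy
        fz = fac * uz
        lforce[li, 0] = fx
        lforce[li, 1] = fy
        lforce[li, 2] = fz
        if include_springs:
            F[f0, k0, 0] += (1.0 - t0) * fx
            F[f0, k0, 1] += (1.0 - t0) * fy
            F[f0, k0, 2] += (1.0 - t0) * fz
            F[f0, k0 + 1, 0] += t0 * fx
            F[f0, k0 + 1, 1] += t0 * fy
            F[f0, k0 + 1, 2] += t0 * fz
            F[f1, k1, 0] -= (1.0 - t1) * fx
            F[f1, k1, 1] -= (1.0 - t1) * fy
            F[f1, k1, 2] -= (1.0 - t1) * fz
            F[f1, k1 + 1, 0] -= t1 * fx
            F[f1, k1 + 1, 1] -= t1 * fy
            F[f1, k1 + 1, 2] -= t1 * fz
        # projections on motion directions (tangent oriented minus->plus)
        for j in range(2):
            fil = lfil[li, j]
            kk, _tt = _anchor_kt(fnv, flast, seg_rest, fil, labs[li, j])
            tx = fverts[fil, kk + 1, 0] - fverts[fil, kk, 0]
            ty = fverts[fil, kk + 1, 1] - fverts[fil, kk, 1]
            tz = fverts[fil, kk + 1, 2] - fverts[fil, kk, 2]
            tn = np.sqrt(tx * tx + ty * ty + tz * tz)
            if tn < 1e-12:
                continue
            sgn = 1.0 if j == 0 else -1.0
            proj = sgn * (fx * tx + fy * ty + fz * tz) / tn
            if u_is_motor[sp, j] == 1:
                lfpar[li, j] = proj * u_dir[sp, j]
            else:
                lfpar[li, j] = proj


@njit(inline="always")
def _precond3(rin, zout, fnv, nf, binv):
    """z = P r, coordinates fused; P = per-filament inverse of the
    implicit bending operator (springs left to the CG)."""
    for fi in range(nf):
        nv = fnv[fi]
        for j in range(nv):
            a0 = 0.0
            a1 = 0.0
            a2 = 0.0
            for k in range(nv):
                w = binv[nv, j, k]
                a0 += w * rin[fi, k, 0]
                a1 += w * rin[fi, k, 1]
                a2 += w * rin[fi, k, 2]
            zout[fi, j, 0] = a0
            zout[fi, j, 1] = a1
            zout[fi, j, 2] = a2


@njit(inline="always")
def _matvec3(xin, yout, fnv, nf, coefkb,
             sp_f0, sp_k0, sp_t0, sp_f1, sp_k1, sp_t1, sp_ck, nspr):
    """y = M x with M = I + (dt/gamma)(K_bend + K_spring), fused over
    the three coordinates."""
    for fi in range(nf):
        nv = fnv[fi]
        for j in range(nv):
            for c in range(3):
                yout[fi, j, c] = xin[fi, j, c]
        for j in range(1, nv - 1):
            for c in range(3):
                sec = (xin[fi, j + 1, c] - 2.0 * xin[fi, j, c]
                       + xin[fi, j - 1, c])
                yout[fi, j + 1, c] += coefkb * sec
                yout[fi, j, c] -= 2.0 * coefkb * sec
                yout[fi, j - 1, c] += coefkb * sec
    for q in range(nspr):
        f0 = sp_f0[q]
        k0 = sp_k0[q]
        t0 = sp_t0[q]
        f1 = sp_f1[q]
        k1 = sp_k1[q]
        t1 = sp_t1[q]
        for c in range(3):
            # s . x  with s = (-(1-t0), -t0, (1-t1), t1)
            sx = (-(1.0 - t0) * xin[f0, k0, c] - t0 * xin[f0, k0 + 1, c]
                  + (1.0 - t1) * xin[f1, k1, c] + t1 * xin[f1, k1 + 1, c])
            tmp = sp_ck[q] * sx  # sp_ck already includes dt k / gamma
            yout[f0, k0, c] += -(1.0 - t0) * tmp
            yout[f0, k0 + 1, c] += -t0 * tmp
            yout[f1, k1, c] += (1.0 - t1) * tmp
            yout[f1, k1 + 1, c] += t1 * tmp


@njit(**_NJIT)
def run_chunk(nsteps,
              fverts, fnv, flen, flast, falpha, nf_a,
              seg_rest, kappa, maxv,
              seeds, seed_used, pool,
              alpha0, sd_factor, clip_lo, clip_hi,
              nuc_rate, growth_end, init_len,
              lx, ly, lz,
              dt, kBT, gamma_v, k_steric, d_steric, cell_min,
              cell_min_bind, binv,
              lspec, lpos, lfil, labs,
              s_k, s_e, s_gfree,
              u_is_motor, u_dir, u_vm, u_fs, u_D, u_kon, u_range,
              u_koff0, u_funb, u_hold,
              time_a,
              F, lforce, lfpar):
    """Advance the system by ``nsteps`` time steps.

    Returns 0 on success, 1 on constraint-solver non-convergence, 2 on
    implicit-solver (CG) non-convergence.
    """
    nl = lspec.shape[0]
    nspec = s_k.shape[0]
    cap = fverts.shape[0]
    coef = dt / gamma_v
    coefkb = coef * kappa / seg_rest ** 3
    sig = np.sqrt(2.0 * kBT * dt / gamma_v) if kBT > 0.0 else 0.0
    pnuc = -np.expm1(-nuc_rate * dt)
    pbind = np.empty((nspec, 2))
    for s in range(nspec):
        for j in range(2):
            pbind[s, j] = -np.expm1(-u_kon[s, j] * dt)
    # implicit-spring assembly workspace
    sp_f0 = np.empty(max(nl, 1), np.int64)
    sp_k0 = np.empty(max(nl, 1), np.int64)
    sp_t0 = np.empty(max(nl, 1))
    sp_f1 = np.empty(max(nl, 1), np.int64)
    sp_k1 = np.empty(max(nl, 1), np.int64)
    sp_t1 = np.empty(max(nl, 1))
    sp_ck = np.empty(max(nl, 1))
    sp_base = np.empty((max(nl, 1), 3))
    # CG workspace (coordinates fused)
    rhs = np.zeros((cap, maxv, 3))
    xv = np.zeros((cap, maxv, 3))
    rr = np.zeros((cap, maxv, 3))
    zz = np.zeros((cap, maxv, 3))
    pp = np.zeros((cap, maxv, 3))
    ap = np.zeros((cap, maxv, 3))
    cand_fil = np.empty(64, np.int64)
    cand_ilo = np.empty(64, np.int64)
    cand_n = np.empty(64, np.int64)
    # constraint-solver workspace
    cn_dh = np.empty((maxv, 3))
    cn_c = np.empty(maxv)
    cn_b = np.empty(maxv)
    cn_e = np.empty(maxv)
    cn_r = np.empty(maxv)

    for _step in range(nsteps):
        nf = nf_a[0]
        t_now = time_a[0]

        # --- deterministic forces (pre-update geometry) ---------------
        # F receives the explicit (steric) forces only; bending and
        # springs are handled by the implicit solve below.
        compute_forces(fverts, fnv, flen, flast, nf, seg_rest, kappa,
                       False, False, lx, ly, k_steric, d_steric, cell_min,
                       lspec, lfil, labs, s_k, s_e, u_is_motor, u_dir,
                       F, lforce, lfpar)

        # --- linearized springs for the implicit operator -------------
        nspr = 0
        for li in range(nl):
            if lfil[li, 0] < 0 or lfil[li, 1] < 0:
                continue
            sp = lspec[li]
            f0 = lfil[li, 0]
            f1 = lfil[li, 1]
            k0, t0 = _anchor_kt(fnv, flast, seg_rest, f0, labs[li, 0])
            k1, t1 = _anchor_kt(fnv, flast, seg_rest, f1, labs[li, 1])
            p0x = (1.0 - t0) * fverts[f0, k0, 0] + t0 * fverts[f0, k0 + 1, 0]
            p0y = (1.0 - t0) * fverts[f0, k0, 1] + t0 * fverts[f0, k0 + 1, 1]
            p0z = (1.0 - t0) * fverts[f0, k0, 2] + t0 * fverts[f0, k0 + 1, 2]
            p1x = (1.0 - t1) * fverts[f1, k1, 0] + t1 * fverts[f1, k1 + 1, 0]
            p1y = (1.0 - t1) * fverts[f1, k1, 1] + t1 * fverts[f1, k1 + 1, 1]
            p1z = (1.0 - t1) * fverts[f1, k1, 2] + t1 * fverts[f1, k1 + 1, 2]
            rawx = p1x - p0x
            rawy = p1y - p0y
            ux = _wrap1(rawx, lx)
            uy = _wrap1(rawy, ly)
            uz = p1z - p0z
            dn = np.sqrt(ux * ux + uy * uy + uz * uz)
            if dn < 1e-12:
                continue
            kk = s_k[sp]
            ee = s_e[sp]
            sp_f0[nspr] = f0
            sp_k0[nspr] = k0
            sp_t0[nspr] = t0
            sp_f1[nspr] = f1
            sp_k1[nspr] = k1
            sp_t1[nspr] = t1
            sp_ck[nspr] = coef * kk
            # constant part of the linearized force: k (shift - e u_hat)
            sp_base[nspr, 0] = kk * ((ux - rawx) - ee * ux / dn)
            sp_base[nspr, 1] = kk * ((uy - rawy) - ee * uy / dn)
            sp_base[nspr, 2] = kk * (-ee * uz / dn)
            nspr += 1

        # --- implicit vertex update: fused 3-coordinate PCG -----------
        for fi in range(nf):
            nv = fnv[fi]
            for j in range(nv):
                for c in range(3):
                    r = fverts[fi, j, c] + coef * F[fi, j, c]
                    if sig > 0.0:
                        r += sig * np.random.normal()
                    rhs[fi, j, c] = r
                    xv[fi, j, c] = fverts[fi, j, c]
        for q in range(nspr):
            t0 = sp_t0[q]
            t1 = sp_t1[q]
            for c in range(3):
                base = coef * sp_base[q, c]
                rhs[sp_f0[q], sp_k0[q], c] += (1.0 - t0) * base
                rhs[sp_f0[q], sp_k0[q] + 1, c] += t0 * base
                rhs[sp_f1[q], sp_k1[q], c] -= (1.0 - t1) * base
                rhs[sp_f1[q], sp_k1[q] + 1, c] -= t1 * base
        _matvec3(xv, ap, fnv, nf, coefkb,
                 sp_f0, sp_k0, sp_t0, sp_f1, sp_k1, sp_t1, sp_ck, nspr)
        for fi in range(nf):
            nv = fnv[fi]
            for j in range(nv):
                for c in range(3):
                    rr[fi, j, c] = rhs[fi, j, c] - ap[fi, j, c]
        _precond3(rr, zz, fnv, nf, binv)
        rz = 0.0
        rnorm = 0.0
        for fi in range(nf):
            nv = fnv[fi]
            for j in range(nv):
                for c in range(3):
                    pp[fi, j, c] = zz[fi, j, c]
                    rz += rr[fi, j, c] * zz[fi, j, c]
                    rnorm += rr[fi, j, c] * rr[fi, j, c]
        # tolerance relative to the initial residual, i.e. to the size
        # of this step's displacement (not to the absolute coordinates)
        tol2 = 1e-10 * rnorm
        converged = rnorm <= 1e-30 or rnorm <= tol2
        for _it in range(400):
            if converged:
                break
            _matvec3(pp, ap, fnv, nf, coefkb,
                     sp_f0, sp_k0, sp_t0, sp_f1, sp_k1, sp_t1, sp_ck, nspr)
            pap = 0.0
            for fi in range(nf):
                nv = fnv[fi]
                for j in range(nv):
                    for c in range(3):
                        pap += pp[fi, j, c] * ap[fi, j, c]
            if pap <= 0.0:
                break
            alpha = rz / pap
            rnorm = 0.0
            for fi in range(nf):
                nv = fnv[fi]
                for j in range(nv):
                    for c in range(3):
                        xv[fi, j, c] += alpha * pp[fi, j, c]
                        rr[fi, j, c] -= alpha * ap[fi, j, c]
                        rnorm += rr[fi, j, c] * rr[fi, j, c]
            if rnorm <= tol2:
                converged = True
                break
            _precond3(rr, zz, fnv, nf, binv)
            rznew = 0.0
            for fi in range(nf):
                nv = fnv[fi]
                for j in range(nv):
                    for c in range(3):
                        rznew += rr[fi, j, c] * zz[fi, j, c]
            beta = rznew / rz
            rz = rznew
            for fi in range(nf):
                nv = fnv[fi]
                for j in range(nv):
                    for c in range(3):
                        pp[fi, j, c] = zz[fi, j, c] + beta * pp[fi, j, c]
        if not converged:
            return 2
        for fi in range(nf):
            nv = fnv[fi]
            for j in range(nv):
                for c in range(3):
                    fverts[fi, j, c] = xv[fi, j, c]

        # --- segment-length constraints and Z reflection --------------
        # Newton iteration on the Lagrange multipliers: each pass
        # solves the tridiagonal Gram system of the constraint
        # gradients exactly and applies the minimal-norm correction.
        for fi in range(nf):
            nv = fnv[fi]
            ok = False
            for _it in range(50):
                maxrel = 0.0
                for j in range(nv - 1):
                    target = seg_rest if j < nv - 2 else flast[fi]
                    dx = fverts[fi, j + 1, 0] - fverts[fi, j, 0]
                    dy = fverts[fi, j + 1, 1] - fverts[fi, j, 1]
                    dz = fverts[fi, j + 1, 2] - fverts[fi, j, 2]
                    dn = np.sqrt(dx * dx + dy * dy + dz * dz)
                    if dn < 1e-12:
                        dx, dy, dz, dn = 1.0, 0.0, 0.0, 1.0
                    cn_dh[j, 0] = dx / dn
                    cn_dh[j, 1] = dy / dn
                    cn_dh[j, 2] = dz / dn
                    cn_c[j] = dn - target
                    rel = abs(cn_c[j]) / target
                    if rel > maxrel:
                        maxrel = rel
                if maxrel < 1e-6:
                    ok = True
                    break
                # Gram matrix: diag 2, off-diag -dhat_j . dhat_{j+1}
                for j in range(nv - 1):
                    cn_b[j] = 2.0
                    cn_r[j] = -cn_c[j]
                for j in range(nv - 2):
                    cn_e[j] = -(cn_dh[j, 0] * cn_dh[j + 1, 0]
                                + cn_dh[j, 1] * cn_dh[j + 1, 1]
                                + cn_dh[j, 2] * cn_dh[j + 1, 2])
                # Thomas elimination (symmetric tridiagonal)
                for j in range(1, nv - 1):
                    w = cn_e[j - 1] / cn_b[j - 1]
                    cn_b[j] -= w * cn_e[j - 1]
                    cn_r[j] -= w * cn_r[j - 1]
                cn_r[nv - 2] /= cn_b[nv - 2]
                for j in range(nv - 3, -1, -1):
                    cn_r[j] = (cn_r[j] - cn_e[j] * cn_r[j + 1]) / cn_b[j]
                # apply dx_v = sum_j lam_j grad_v C_j
                for j in range(nv - 1):
                    lam = cn_r[j]
                    for c in range(3):
                        fverts[fi, j, c] -= lam * cn_dh[j, c]
                        fverts[fi, j + 1, c] += lam * cn_dh[j, c]
            if not ok:
                return 1
            for j in range(nv):
                z = fverts[fi, j, 2]
                if z < 0.0 or z > lz:
                    z = z % (2.0 * lz)
                    if z > lz:
                        z = 2.0 * lz - z
                    fverts[fi, j, 2] = z

        # --- linker kinetics (rates from pre-update forces) -----------
        if nl > 0:
            # finer grid than the steric one: binding queries only need
            # to reach half a segment plus the capture radius
            seg_fil, seg_k, order, startc, ncx, ncy, use_cells = \
                _build_cells(fverts, fnv, nf, lx, ly, cell_min_bind)
            mseg = seg_fil.shape[0]
            csx = lx / ncx
            csy = ly / ncy
            for li in range(nl):
                sp = lspec[li]
                both = lfil[li, 0] >= 0 and lfil[li, 1] >= 0
                fmag = 0.0
                if both:
                    fmag = np.sqrt(lforce[li, 0] ** 2 + lforce[li, 1] ** 2
                                   + lforce[li, 2] ** 2)
                # unbinding and movement of bound units
                for j in range(2):
                    fil = lfil[li, j]
                    if fil < 0:
                        continue
                    koff = u_koff0[sp, j] * np.exp(
                        min(fmag / u_funb[sp, j], 40.0))
                    if np.random.random() < -np.expm1(-koff * dt):
                        if lfil[li, 1 - j] < 0:
                            kk, tt = _anchor_kt(fnv, flast, seg_rest, fil,
                                                labs[li, j])
                            for c in range(3):
                                lpos[li, c] = ((1.0 - tt) * fverts[fil, kk, c]
                                               + tt * fverts[fil, kk + 1, c])
                            lpos[li, 0] -= lx * np.floor(lpos[li, 0] / lx)
                            lpos[li, 1] -= ly * np.floor(lpos[li, 1] / ly)
                        lfil[li, j] = -1
                        continue
                    L = flen[fil]
                    fp = lfpar[li, j] if both else 0.0
                    a = labs[li, j]
                    if u_is_motor[sp, j] == 1:
                        v = u_vm[sp, j] * (1.0 + fp / u_fs[sp, j])
                        if v < 0.0:
                            v = 0.0
                        elif v > 2.0 * u_vm[sp, j]:
                            v = 2.0 * u_vm[sp, j]
                        lam = v * dt / LATTICE
                        n = np.random.poisson(lam) if lam > 0.0 else 0
                        a = a + u_dir[sp, j] * n * LATTICE
                    else:
                        if u_D[sp, j] > 0.0:
                            r0 = u_D[sp, j] / (LATTICE * LATTICE)
                            x = 0.0
                            if kBT > 0.0:
                                x = fp * LATTICE / (2.0 * kBT)
                                if x > 40.0:
                                    x = 40.0
                                elif x < -40.0:
                                    x = -40.0
                            npl = np.random.poisson(r0 * np.exp(x) * dt)
                            nmi = np.random.poisson(r0 * np.exp(-x) * dt)
                            a = a + (npl - nmi) * LATTICE
                    at_minus = a <= 0.0
                    at_plus = a >= L
                    if at_minus:
                        a = 0.0
                    if at_plus:
                        a = L
                    labs[li, j] = a
                    if (at_minus or at_plus) and u_hold[sp, j] == 0:
                        if u_is_motor[sp, j] == 1:
                            release = at_plus if u_dir[sp, j] > 0 else at_minus
                        else:
                            release = True
                        if release:
                            if lfil[li, 1 - j] < 0:
                                kk, tt = _anchor_kt(fnv, flast, seg_rest,
                                                    fil, a)
                                for c in range(3):
                                    lpos[li, c] = (
                                        (1.0 - tt) * fverts[fil, kk, c]
                                        + tt * fverts[fil, kk + 1, c])
                                lpos[li, 0] -= lx * np.floor(lpos[li, 0] / lx)
                                lpos[li, 1] -= ly * np.floor(lpos[li, 1] / ly)
                            lfil[li, j] = -1

                # free diffusion of a fully unbound complex
                if lfil[li, 0] < 0 and lfil[li, 1] < 0:
                    sl = np.sqrt(2.0 * kBT * dt / s_gfree[sp]) \
                        if kBT > 0.0 else 0.0
                    if sl > 0.0:
                        for c in range(3):
                            lpos[li, c] += sl * np.random.normal()
                        lpos[li, 0] -= lx * np.floor(lpos[li, 0] / lx)
                        lpos[li, 1] -= ly * np.floor(lpos[li, 1] / ly)
                        z = lpos[li, 2]
                        if z < 0.0 or z > lz:
                            z = z % (2.0 * lz)
                            if z > lz:
                                z = 2.0 * lz - z
                            lpos[li, 2] = z

                # binding attempts of unbound units
                if mseg == 0:
                    continue
                for j in range(2):
                    if lfil[li, j] >= 0:
                        continue
                    if np.random.random() >= pbind[sp, j]:
                        continue
                    partner = lfil[li, 1 - j]
                    if partner >= 0:
                        kk, tt = _anchor_kt(fnv, flast, seg_rest, partner,
                                            labs[li, 1 - j])
                        cx0 = ((1.0 - tt) * fverts[partner, kk, 0]
                               + tt * fverts[partner, kk + 1, 0])
                        cy0 = ((1.0 - tt) * fverts[partner, kk, 1]
                               + tt * fverts[partner, kk + 1, 1])
                        cz0 = ((1.0 - tt) * fverts[partner, kk, 2]
                               + tt * fverts[partner, kk + 1, 2])
                    else:
                        cx0 = lpos[li, 0]
                        cy0 = lpos[li, 1]
                        cz0 = lpos[li, 2]
                    rng2 = u_range[sp, j] * u_range[sp, j]
                    ncand = 0
                    ntot = 0
                    if use_cells:
                        mx = cx0 - lx * np.floor(cx0 / lx)
                        my = cy0 - ly * np.floor(cy0 / ly)
                        ccx = min(int(mx / csx), ncx - 1)
                        ccy = min(int(my / csy), ncy - 1)
                        for oy in range(-1, 2):
                            for ox in range(-1, 2):
                                cc = (((ccy + oy) % ncy) * ncx
                                      + (ccx + ox) % ncx)
                                for bb in range(startc[cc], startc[cc + 1]):
                                    ncand, ntot = _scan_segment(
                                        fverts, fnv, flen, flast, seg_rest,
                                        seg_fil, seg_k, order[bb], partner,
                                        cx0, cy0, cz0, rng2, lx, ly,
                                        cand_fil, cand_ilo, cand_n,
                                        ncand, ntot)
                    else:
                        for s2 in range(mseg):
                            ncand, ntot = _scan_segment(
                                fverts, fnv, flen, flast, seg_rest,
                                seg_fil, seg_k, s2, partner,
                                cx0, cy0, cz0, rng2, lx, ly,
                                cand_fil, cand_ilo, cand_n, ncand, ntot)
                    if ntot <= 0:
                        continue
                    pick = np.random.randint(0, ntot)
                    for q in range(ncand):
                        if pick < cand_n[q]:
                            site = cand_ilo[q] + pick
                            fil2 = cand_fil[q]
                            aa = (site + 0.5) * LATTICE
                            if aa > flen[fil2]:
                                aa = flen[fil2]
                            lfil[li, j] = fil2
                            labs[li, j] = aa
                            break
                        pick -= cand_n[q]

        # --- nucleation and pool-limited growth -----------------------
        if t_now < growth_end:
            ns = seeds.shape[0]
            for si in range(ns):
                if seed_used[si] == 1:
                    continue
                if np.random.random() < pnuc:
                    avail = pool[0] - pool[1]
                    if avail <= 1e-12:
                        continue
                    l0 = min(init_len, avail)
                    fi = nf_a[0]
                    if fi >= fnv.shape[0]:
                        continue
                    th = np.random.random() * 6.283185307179586
                    dx = np.cos(th)
                    dy = np.sin(th)
                    for c in range(3):
                        fverts[fi, 0, c] = seeds[si, c]
                        fverts[fi, 1, c] = seeds[si, c]
                    fverts[fi, 0, 0] -= 0.5 * l0 * dx
                    fverts[fi, 0, 1] -= 0.5 * l0 * dy
                    fverts[fi, 1, 0] += 0.5 * l0 * dx
                    fverts[fi, 1, 1] += 0.5 * l0 * dy
                    fnv[fi] = 2
                    flen[fi] = l0
                    flast[fi] = l0
                    al = alpha0 * abs(1.0 + sd_factor * np.random.normal())
                    if al < clip_lo:
                        al = clip_lo
                    elif al > clip_hi:
                        al = clip_hi
                    falpha[fi] = al
                    seed_used[si] = 1
                    nf_a[0] = fi + 1
                    pool[1] += l0
            nf = nf_a[0]
            for fi in range(nf):
                nv = fnv[fi]
                if nv >= maxv and flast[fi] >= 1.5 * seg_rest - 1e-9:
                    continue  # vertex capacity reached; growth halts
                vg = falpha[fi] * (1.0 - pool[1] / pool[0])
                if vg <= 0.0:
                    continue
                dl = vg * dt
                avail = pool[0] - pool[1]
                if dl > avail:
                    dl = avail
                if dl <= 0.0:
                    continue
                dxx = fverts[fi, nv - 1, 0] - fverts[fi, nv - 2, 0]
                dyy = fverts[fi, nv - 1, 1] - fverts[fi, nv - 2, 1]
                dzz = fverts[fi, nv - 1, 2] - fverts[fi, nv - 2, 2]
                dn = np.sqrt(dxx * dxx + dyy * dyy + dzz * dzz)
                if dn < 1e-12:
                    dxx, dyy, dzz, dn = 1.0, 0.0, 0.0, 1.0
                fverts[fi, nv - 1, 0] += dl * dxx / dn
                fverts[fi, nv - 1, 1] += dl * dyy / dn
                fverts[fi, nv - 1, 2] += dl * dzz / dn
                flast[fi] += dl
                flen[fi] += dl
                pool[1] += dl
                if flast[fi] > 1.5 * seg_rest and nv < maxv:
                    # split the terminal segment: insert a vertex at
                    # rest-length distance from the penultimate one
                    ex = fverts[fi, nv - 1, 0]
                    ey = fverts[fi, nv - 1, 1]
                    ez = fverts[fi, nv - 1, 2]
                    ux = (ex - fverts[fi, nv - 2, 0]) / flast[fi]
                    uy = (ey - fverts[fi, nv - 2, 1]) / flast[fi]
                    uz = (ez - fverts[fi, nv - 2, 2]) / flast[fi]
                    fverts[fi, nv - 1, 0] = fverts[fi, nv - 2, 0] + seg_rest * ux
                    fverts[fi, nv - 1, 1] = fverts[fi, nv - 2, 1] + seg_rest * uy
                    fverts[fi, nv - 1, 2] = fverts[fi, nv - 2, 2] + seg_rest * uz
                    fverts[fi, nv, 0] = ex
                    fverts[fi, nv, 1] = ey
                    fverts[fi, nv, 2] = ez
                    fnv[fi] = nv + 1
                    flast[fi] -= seg_rest

        time_a[0] = t_now + dt
    return 0


@njit(inline="always")
def _scan_segment(fverts, fnv, flen, flast, seg_rest, seg_fil, seg_k, s2,
                  partner, cx0, cy0, cz0, rng2, lx, ly,
                  cand_fil, cand_ilo, cand_n, ncand, ntot):
    """Collect the lattice sites of one segment lying within binding
    range of a point; appends to the candidate interval list."""
    fil = seg_fil[s2]
    if fil == partner or ncand >= 64:
        return ncand, ntot
    k = seg_k[s2]
    px = fverts[fil, k, 0]
    py = fverts[fil, k, 1]
    pz = fverts[fil, k, 2]
    ux = fverts[fil, k + 1, 0] - px
    uy = fverts[fil, k + 1, 1] - py
    uz = fverts[fil, k + 1, 2] - pz
    wx = _wrap1(cx0 - px, lx)
    wy = _wrap1(cy0 - py, ly)
    wz = cz0 - pz
    uu = ux * ux + uy * uy + uz * uz
    if uu < 1e-14:
        return ncand, ntot
    uw = ux * wx + uy * wy + uz * wz
    ww = wx * wx + wy * wy + wz * wz
    disc = uw * uw - uu * (ww - rng2)
    if disc <= 0.0:
        return ncand, ntot
    sq = np.sqrt(disc)
    tlo = (uw - sq) / uu
    thi = (uw + sq) / uu
    if tlo < 0.0:
        tlo = 0.0
    if thi > 1.0:
        thi = 1.0
    if tlo >= thi:
        return ncand, ntot
    slen = np.sqrt(uu)
    base = k * seg_rest
    alo = base + tlo * slen
    ahi = base + thi * slen
    L = flen[fil]
    if ahi > L:
        ahi = L
    ilo = int(np.ceil(alo / LATTICE - 0.5))
    ihi = int(np.floor(ahi / LATTICE - 0.5))
    if ilo < 0:
        ilo = 0
    if ihi < ilo:
        return ncand, ntot
    cand_fil[ncand] = fil
    cand_ilo[ncand] = ilo
    cand_n[ncand] = ihi - ilo + 1
    return ncand + 1, ntot + ihi - ilo + 1
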