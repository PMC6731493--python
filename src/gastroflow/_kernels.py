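"""Numba kernels for the free-surface MRT lattice Boltzmann solver.

Grid layout: distributions ``f[nx, ny, nz, 19]`` (lattice units), node flags
``flags[nx, ny, nz]`` with the codes below, level set ``psi`` (signed
distance to the instantaneous wall in units of dx, negative in the lumen),
and per-cell liquid mass ``mass`` (Koerner-style free-surface tracking:
liquid cells carry m = rho, interface cells 0 <= m <= rho, gas cells 0).

Streaming is pull-form with periodic index wrap; non-periodic boundaries
are realized by solid padding.  Wall links use linear-interpolated
(Bouzidi) bounce-back with the moving-wall momentum term; links from gas
are reconstructed from the atmospheric-pressure equilibrium.

Mass that cannot be placed locally (cells covered/uncovered by the moving
wall, conversion leftovers) goes into a global reservoir redistributed
uniformly over interface cells each step, keeping the global balance exact
up to outlet flux and interpolation error.
"""

import numpy as np
from numba import njit

GAS = 0
INTERFACE = 1
LIQUID = 2
SOLID = 3
TO_LIQ = 11
TO_GAS = 12

_F8 = "(cache=True)"


@njit(cache=True)
def build_active(flags, ii, jj, kk):
    """Collect indices of liquid and interface cells."""
    nx, ny, nz = flags.shape
    n = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                fl = flags[i, j, k]
                if fl == LIQUID or fl == INTERFACE:
                    ii[n] = i
                    jj[n] = j
                    kk[n] = k
                    n += 1
    return n


@njit(cache=True, fastmath=True)
def macro_collide(f, fpost, flags, ii, jj, kk, n, A, fx, fy, fz,
                  rho, ux, uy, uz, mass, CX, CY, CZ, W):
    """Macroscopic moments + MRT collision with Guo forcing.

    ``A = M^-1 S M`` is the velocity-space collision matrix.  Velocities are
    force-shifted (u = (sum f c + F/2)/rho) and clamped at |u_a| <= 0.4 as a
    stability guard; the clamp count is returned for diagnostics.
    """
    nclamp = 0
    fe = np.empty(19)
    g = np.empty(19)
    for m in range(n):
        i = ii[m]; j = jj[m]; k = kk[m]
        r = 0.0; jx = 0.0; jy = 0.0; jz = 0.0
        for q in range(19):
            fq = f[i, j, k, q]
            r += fq
            jx += fq * CX[q]
            jy += fq * CY[q]
            jz += fq * CZ[q]
        Fx = fx[i, j, k]; Fy = fy[i, j, k]; Fz = fz[i, j, k]
        if r < 1e-6:
            r = 1e-6
        uxv = (jx + 0.5 * Fx) / r
        uyv = (jy + 0.5 * Fy) / r
        uzv = (jz + 0.5 * Fz) / r
        lim = 0.4
        if uxv > lim or uxv < -lim or uyv > lim or uyv < -lim or uzv > lim or uzv < -lim:
            nclamp += 1
            if uxv > lim: uxv = lim
            if uxv < -lim: uxv = -lim
            if uyv > lim: uyv = lim
            if uyv < -lim: uyv = -lim
            if uzv > lim: uzv = lim
            if uzv < -lim: uzv = -lim
        rho[i, j, k] = r
        ux[i, j, k] = uxv
        uy[i, j, k] = uyv
        uz[i, j, k] = uzv
        if flags[i, j, k] == LIQUID:
            mass[i, j, k] = r
        usq = 1.5 * (uxv * uxv + uyv * uyv + uzv * uzv)
        uF = uxv * Fx + uyv * Fy + uzv * Fz
        for q in range(19):
            cu = CX[q] * uxv + CY[q] * uyv + CZ[q] * uzv
            fe[q] = W[q] * r * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
            cF = CX[q] * Fx + CY[q] * Fy + CZ[q] * Fz
            Fq = W[q] * (3.0 * cF + 9.0 * cu * cF - 3.0 * uF)
            g[q] = (f[i, j, k, q] - fe[q]) + 0.5 * Fq
            fpost[i, j, k, q] = f[i, j, k, q] + Fq
        for q in range(19):
            acc = 0.0
            for p in range(19):
                acc += A[q, p] * g[p]
            fpost[i, j, k, q] -= acc
    return nclamp


@njit(cache=True, fastmath=True)
def stream(fpost, f, flags, psi, uwx, uwy, uwz, rho, ux, uy, uz, mass,
           ii, jj, kk, n, CX, CY, CZ, OPP, W, rho_atm, use_interp):
    """Pull streaming with Bouzidi bounce-back, gas reconstruction, mass exchange.

    Returns the total mass-exchange residual absorbed at degenerate links
    (diagnostic; normally 0).
    """
    nx, ny, nz = flags.shape
    for m in range(n):
        i = ii[m]; j = jj[m]; k = kk[m]
        fl = flags[i, j, k]
        f[i, j, k, 0] = fpost[i, j, k, 0]
        dm = 0.0
        uxv = ux[i, j, k]; uyv = uy[i, j, k]; uzv = uz[i, j, k]
        usq = 1.5 * (uxv * uxv + uyv * uyv + uzv * uzv)
        for q in range(1, 19):
            si = i - CX[q]
            if si < 0: si += nx
            elif si >= nx: si -= nx
            sj = j - CY[q]
            if sj < 0: sj += ny
            elif sj >= ny: sj -= ny
            sk = k - CZ[q]
            if sk < 0: sk += nz
            elif sk >= nz: sk -= nz
            sf = flags[si, sj, sk]
            o = OPP[q]
            if sf == LIQUID or sf == INTERFACE:
                fin = fpost[si, sj, sk, q]
                f[i, j, k, q] = fin
                if fl == INTERFACE or sf == INTERFACE:
                    fout = fpost[i, j, k, o]
                    if fl == INTERFACE and sf == INTERFACE:
                        ka = mass[i, j, k] / rho[i, j, k]
                        kb = mass[si, sj, sk] / rho[si, sj, sk]
                        if ka < 0.0: ka = 0.0
                        if ka > 1.0: ka = 1.0
                        if kb < 0.0: kb = 0.0
                        if kb > 1.0: kb = 1.0
                        dm += (fin - fout) * 0.5 * (ka + kb)
                    elif fl == INTERFACE:
                        dm += fin - fout
                    # liquid cell mass is slaved to rho; no explicit update
            elif sf == GAS:
                # free-surface reconstruction from atmospheric equilibrium
                cu = CX[q] * uxv + CY[q] * uyv + CZ[q] * uzv
                feq_q = W[q] * rho_atm * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
                # opposite direction has cu -> -cu
                feq_o = W[q] * rho_atm * (1.0 - 3.0 * cu + 4.5 * cu * cu - usq)
                f[i, j, k, q] = feq_q + feq_o - fpost[i, j, k, o]
            else:
                # SOLID: linear-interpolated bounce-back with moving wall
                if use_interp == 1:
                    pa = psi[i, j, k]
                    pb = psi[si, sj, sk]
                    denom = pa - pb
                    if denom < -1e-9:
                        qf = pa / denom
                    else:
                        qf = 0.5
                else:
                    qf = 0.5  # half-way bounce-back (exactly mass conserving)
                if qf < 0.0: qf = 0.0
                if qf > 1.0: qf = 1.0
                mom = 6.0 * W[q] * rho[i, j, k] * (
                    CX[q] * uwx[si, sj, sk] + CY[q] * uwy[si, sj, sk] + CZ[q] * uwz[si, sj, sk]
                )
                if qf >= 0.5:
                    f[i, j, k, q] = (fpost[i, j, k, o] + (2.0 * qf - 1.0) * fpost[i, j, k, q] + mom) / (2.0 * qf)
                else:
                    bi = i + CX[q]
                    if bi < 0: bi += nx
                    elif bi >= nx: bi -= nx
                    bj = j + CY[q]
                    if bj < 0: bj += ny
                    elif bj >= ny: bj -= ny
                    bk = k + CZ[q]
                    if bk < 0: bk += nz
                    elif bk >= nz: bk -= nz
                    bf = flags[bi, bj, bk]
                    if bf == LIQUID or bf == INTERFACE:
                        f[i, j, k, q] = (2.0 * qf * fpost[i, j, k, o]
                                         + (1.0 - 2.0 * qf) * fpost[bi, bj, bk, o] + mom)
                    else:
                        f[i, j, k, q] = fpost[i, j, k, o] + mom
        if fl == INTERFACE:
            mass[i, j, k] += dm
    return 0.0


@njit(cache=True, fastmath=True)
def outlet_bc(f, flags, oi, oj, ok, n_out, dix, diy, diz, CX, CY, CZ, W, rho_out):
    """Constant-pressure non-reflecting outlet (Guo extrapolation).

    Each outlet cell copies the non-equilibrium part of its inward
    neighbour and takes the equilibrium at the outlet density with the
    neighbour's velocity.  Returns the mass removed by the overwrite --
    the outlet layer only exchanges with the interior, so this *is* the
    outflow volume (in cell-mass units) for exact bookkeeping.
    """
    removed = 0.0
    for m in range(n_out):
        i = oi[m]; j = oj[m]; k = ok[m]
        ni = i + dix; nj = j + diy; nk = k + diz
        r = 0.0; jx = 0.0; jy = 0.0; jz = 0.0
        for q in range(19):
            fq = f[ni, nj, nk, q]
            r += fq
            jx += fq * CX[q]
            jy += fq * CY[q]
            jz += fq * CZ[q]
        if r < 1e-6:
            r = 1e-6
        uxv = jx / r; uyv = jy / r; uzv = jz / r
        usq = 1.5 * (uxv * uxv + uyv * uyv + uzv * uzv)
        for q in range(19):
            cu = CX[q] * uxv + CY[q] * uyv + CZ[q] * uzv
            fe_out = W[q] * rho_out * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
            fe_nb = W[q] * r * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
            removed += f[i, j, k, q] - (fe_out + (f[ni, nj, nk, q] - fe_nb))
            f[i, j, k, q] = fe_out + (f[ni, nj, nk, q] - fe_nb)
    return removed


@njit(cache=True, fastmath=True)
def convert_cells(flags, mass, rho, ux, uy, uz, f, ii, jj, kk, n, CX, CY, CZ, W, tol):
    """Interface cell conversion with closed-layer repair.

    Overfull interface cells become liquid, emptied ones gas; the interface
    layer is kept closed by flagging new neighbours, and excess/deficit
    mass is pushed to neighbouring interface cells (leftover returned to
    the global reservoir).  ``ii/jj/kk[:n]`` is the active-cell list from
    this step; all conversions happen in its neighbourhood.
    """
    nx, ny, nz = flags.shape
    leftover = 0.0
    # pass 1 over active interface cells: mark overfull/empty, plus layer
    # cleanup -- no gas neighbour means bulk, no liquid neighbour and
    # nearly empty means gas; keeps the interface one cell thick
    nconv = 0
    conv = np.empty((n, 3), np.int64)
    for m0 in range(n):
        i = ii[m0]; j = jj[m0]; k = kk[m0]
        if flags[i, j, k] != INTERFACE:
            continue
        m = mass[i, j, k]
        r = rho[i, j, k]
        mark = 0
        if m > r * (1.0 + tol):
            mark = TO_LIQ
        elif m < -tol:
            mark = TO_GAS
        else:
            has_gas = False
            has_liq = False
            for q in range(1, 19):
                bi = (i + CX[q]) % nx
                bj = (j + CY[q]) % ny
                bk = (k + CZ[q]) % nz
                bf = flags[bi, bj, bk]
                if bf == GAS:
                    has_gas = True
                elif bf == LIQUID:
                    has_liq = True
            if not has_gas:
                mark = TO_LIQ
            elif not has_liq and m < 0.1 * r:
                mark = TO_GAS
        if mark != 0:
            flags[i, j, k] = mark
            conv[nconv, 0] = i; conv[nconv, 1] = j; conv[nconv, 2] = k
            nconv += 1
    # pass 2: new liquid cells need an interface shell on the gas side
    for m0 in range(nconv):
        i = conv[m0, 0]; j = conv[m0, 1]; k = conv[m0, 2]
        if flags[i, j, k] != TO_LIQ:
            continue
        for q in range(1, 19):
            bi = (i + CX[q]) % nx
            bj = (j + CY[q]) % ny
            bk = (k + CZ[q]) % nz
            if flags[bi, bj, bk] == GAS:
                # init from average of surrounding wet cells
                r_s = 0.0; ux_s = 0.0; uy_s = 0.0; uz_s = 0.0; cnt = 0
                for p in range(1, 19):
                    ci = (bi + CX[p]) % nx
                    cj = (bj + CY[p]) % ny
                    ck = (bk + CZ[p]) % nz
                    cf = flags[ci, cj, ck]
                    if cf == LIQUID or cf == INTERFACE or cf == TO_LIQ:
                        r_s += rho[ci, cj, ck]
                        ux_s += ux[ci, cj, ck]
                        uy_s += uy[ci, cj, ck]
                        uz_s += uz[ci, cj, ck]
                        cnt += 1
                if cnt > 0:
                    r_s /= cnt; ux_s /= cnt; uy_s /= cnt; uz_s /= cnt
                else:
                    r_s = 1.0
                usq = 1.5 * (ux_s * ux_s + uy_s * uy_s + uz_s * uz_s)
                for p in range(19):
                    cu = CX[p] * ux_s + CY[p] * uy_s + CZ[p] * uz_s
                    f[bi, bj, bk, p] = W[p] * r_s * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
                rho[bi, bj, bk] = r_s
                ux[bi, bj, bk] = ux_s
                uy[bi, bj, bk] = uy_s
                uz[bi, bj, bk] = uz_s
                mass[bi, bj, bk] = 0.0
                flags[bi, bj, bk] = INTERFACE
    # pass 3: new gas cells need their liquid neighbours demoted to interface
    for m0 in range(nconv):
        i = conv[m0, 0]; j = conv[m0, 1]; k = conv[m0, 2]
        if flags[i, j, k] != TO_GAS:
            continue
        for q in range(1, 19):
            bi = (i + CX[q]) % nx
            bj = (j + CY[q]) % ny
            bk = (k + CZ[q]) % nz
            if flags[bi, bj, bk] == LIQUID:
                flags[bi, bj, bk] = INTERFACE
                mass[bi, bj, bk] = rho[bi, bj, bk]
    # pass 4: distribute excess/deficit, finalize
    for m0 in range(nconv):
        i = conv[m0, 0]; j = conv[m0, 1]; k = conv[m0, 2]
        fl = flags[i, j, k]
        if fl == TO_LIQ:
            extra = mass[i, j, k] - rho[i, j, k]
        else:
            extra = mass[i, j, k]
        cnt = 0
        for q in range(1, 19):
            bi = (i + CX[q]) % nx
            bj = (j + CY[q]) % ny
            bk = (k + CZ[q]) % nz
            if flags[bi, bj, bk] == INTERFACE:
                cnt += 1
        if cnt > 0:
            share = extra / cnt
            for q in range(1, 19):
                bi = (i + CX[q]) % nx
                bj = (j + CY[q]) % ny
                bk = (k + CZ[q]) % nz
                if flags[bi, bj, bk] == INTERFACE:
                    mass[bi, bj, bk] += share
        else:
            leftover += extra
        if fl == TO_LIQ:
            mass[i, j, k] = rho[i, j, k]
            flags[i, j, k] = LIQUID
        else:
            mass[i, j, k] = 0.0
            flags[i, j, k] = GAS
            for q in range(19):
                f[i, j, k, q] = 0.0
    return leftover


@njit(cache=True, fastmath=True)
def apply_wall_motion(flags, psi, movable, mass, rho, ux, uy, uz, f,
                      uwx, uwy, uwz, CX, CY, CZ, W):
    """Reclassify cells covered/uncovered by the moving wall.

    Covered wet cells give their mass to the reservoir (returned); cells
    uncovered next to wet cells are re-activated as liquid at the local
    average density (charged to the reservoir), next to gas as gas.
    """
    nx, ny, nz = flags.shape
    reservoir = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not movable[i, j, k]:
                    continue
                fl = flags[i, j, k]
                p = psi[i, j, k]
                if (fl == LIQUID or fl == INTERFACE) and p >= 0.0:
                    reservoir += mass[i, j, k]
                    mass[i, j, k] = 0.0
                    flags[i, j, k] = SOLID
                    for q in range(19):
                        f[i, j, k, q] = 0.0
                elif fl == GAS and p >= 0.0:
                    flags[i, j, k] = SOLID
                elif fl == SOLID and p < 0.0:
                    wet = 0
                    gas = 0
                    r_s = 0.0; cnt = 0
                    for q in range(1, 19):
                        bi = (i + CX[q]) % nx
                        bj = (j + CY[q]) % ny
                        bk = (k + CZ[q]) % nz
                        bf = flags[bi, bj, bk]
                        if bf == LIQUID or bf == INTERFACE:
                            wet += 1
                            r_s += rho[bi, bj, bk]
                            cnt += 1
                        elif bf == GAS:
                            gas += 1
                    if wet > 0:
                        r_s /= cnt
                        uxw = uwx[i, j, k]; uyw = uwy[i, j, k]; uzw = uwz[i, j, k]
                        usq = 1.5 * (uxw * uxw + uyw * uyw + uzw * uzw)
                        for q in range(19):
                            cu = CX[q] * uxw + CY[q] * uyw + CZ[q] * uzw
                            f[i, j, k, q] = W[q] * r_s * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
                        rho[i, j, k] = r_s
                        ux[i, j, k] = uxw
                        uy[i, j, k] = uyw
                        uz[i, j, k] = uzw
                        mass[i, j, k] = r_s
                        flags[i, j, k] = LIQUID
                        reservoir -= r_s
                    elif gas > 0:
                        flags[i, j, k] = GAS
                    # else: stays solid until a neighbour opens
    return reservoir


@njit(cache=True)
def distribute_reservoir(flags, mass, amount, cap):
    """Spread the global mass reservoir uniformly over interface cells.

    The per-cell share is rate-limited to ``cap`` per step (surface rises
    and falls smoothly even when the wall covers many cells at once); the
    undistributed remainder is returned.
    """
    nx, ny, nz = flags.shape
    cnt = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if flags[i, j, k] == INTERFACE:
                    cnt += 1
    if cnt == 0:
        return amount
    share = amount / cnt
    if share > cap:
        share = cap
    elif share < -cap:
        share = -cap
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if flags[i, j, k] == INTERFACE:
                    mass[i, j, k] += share
    return amount - share * cnt


@njit(cache=True)
def total_mass(flags, mass):
    nx, ny, nz = flags.shape
    s = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                fl = flags[i, j, k]
                if fl == LIQUID or fl == INTERFACE:
                    s += mass[i, j, k]
    return s
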