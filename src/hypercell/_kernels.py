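"""Numba-compiled inner loops: elastic force assembly and the D3Q19
lattice-Boltzmann / immersed-boundary kernels.

Everything here operates on plain float64/int64 arrays; the user-facing
wrappers live in :mod:`hypercell.forces` and :mod:`hypercell.flow`.  The
per-element partial derivatives of the Mooney-Rivlin energy follow the chain
rule through (tr C, tr C^2, det F); accumulation order over elements is fixed
(ascending element index) so results are reproducible run to run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# elastic forces
# ---------------------------------------------------------------------------


@njit(cache=True)
def elastic_force_energy(tets, B, V0, disp, mu1, mu2, kappa, forces):
    """Accumulate per-vertex elastic forces into ``forces`` (must be zeroed)
    and return ``(total_energy, bad_element)``.

    ``bad_element`` is -1 on success, else the index of the first element
    with det F <= 0 (in which case energy/forces are invalid).
    """
    n_t = tets.shape[0]
    energy = 0.0
    for t in range(n_t):
        i0 = tets[t, 0]
        i1 = tets[t, 1]
        i2 = tets[t, 2]
        i3 = tets[t, 3]
        # displacement matrix A, columns k = u^k - u^4
        a00 = disp[i0, 0] - disp[i3, 0]
        a10 = disp[i0, 1] - disp[i3, 1]
        a20 = disp[i0, 2] - disp[i3, 2]
        a01 = disp[i1, 0] - disp[i3, 0]
        a11 = disp[i1, 1] - disp[i3, 1]
        a21 = disp[i1, 2] - disp[i3, 2]
        a02 = disp[i2, 0] - disp[i3, 0]
        a12 = disp[i2, 1] - disp[i3, 1]
        a22 = disp[i2, 2] - disp[i3, 2]
        b = B[t]
        # F = A_col @ B + I  with A_col columns (a0*, a1*, a2*)
        f00 = a00 * b[0, 0] + a01 * b[1, 0] + a02 * b[2, 0] + 1.0
        f01 = a00 * b[0, 1] + a01 * b[1, 1] + a02 * b[2, 1]
        f02 = a00 * b[0, 2] + a01 * b[1, 2] + a02 * b[2, 2]
        f10 = a10 * b[0, 0] + a11 * b[1, 0] + a12 * b[2, 0]
        f11 = a10 * b[0, 1] + a11 * b[1, 1] + a12 * b[2, 1] + 1.0
        f12 = a10 * b[0, 2] + a11 * b[1, 2] + a12 * b[2, 2]
        f20 = a20 * b[0, 0] + a21 * b[1, 0] + a22 * b[2, 0]
        f21 = a20 * b[0, 1] + a21 * b[1, 1] + a22 * b[2, 1]
        f22 = a20 * b[0, 2] + a21 * b[1, 2] + a22 * b[2, 2] + 1.0

        J = (f00 * (f11 * f22 - f12 * f21)
             - f01 * (f10 * f22 - f12 * f20)
             + f02 * (f10 * f21 - f11 * f20))
        if J <= 0.0:
            return np.nan, t

        # C = F^T F (symmetric)
        c00 = f00 * f00 + f10 * f10 + f20 * f20
        c11 = f01 * f01 + f11 * f11 + f21 * f21
        c22 = f02 * f02 + f12 * f12 + f22 * f22
        c01 = f00 * f01 + f10 * f11 + f20 * f21
        c02 = f00 * f02 + f10 * f12 + f20 * f22
        c12 = f01 * f02 + f11 * f12 + f21 * f22
        TC = c00 + c11 + c22
        TC2 = (c00 * c00 + c11 * c11 + c22 * c22
               + 2.0 * (c01 * c01 + c02 * c02 + c12 * c12))

        Jm23 = J ** (-2.0 / 3.0)
        Jm43 = Jm23 * Jm23
        Jm53 = Jm23 / J
        Jm73 = Jm43 / J

        I1 = TC * Jm23
        K1 = 0.5 * (TC * TC - TC2) * Jm43
        energy += V0[t] * (0.5 * mu1 * (I1 - 3.0) + 0.5 * mu2 * (K1 - 3.0)
                           + 0.5 * kappa * (J - 1.0) * (J - 1.0))

        # dU/dF_il = c1 * dTC/dF + c2 * dJ/dF + c3 * dTC2/dF
        #   dTC/dF_il = 2 F_il ; dJ/dF_il = J F^-1_li ; dTC2/dF_il = 4 (F C)_il
        c1 = 0.5 * mu1 * Jm23 + 0.5 * mu2 * TC * Jm43
        c2 = (0.5 * mu1 * (-2.0 / 3.0) * TC * Jm53
              + 0.5 * mu2 * (-2.0 / 3.0) * (TC * TC - TC2) * Jm73
              + kappa * (J - 1.0))
        c3 = -0.25 * mu2 * Jm43

        # dJ/dF_il = J F^{-1}_{li} = cofactor(F)_{il}
        g00 = f11 * f22 - f12 * f21
        g01 = f12 * f20 - f10 * f22
        g02 = f10 * f21 - f11 * f20
        g10 = f02 * f21 - f01 * f22
        g11 = f00 * f22 - f02 * f20
        g12 = f01 * f20 - f00 * f21
        g20 = f01 * f12 - f02 * f11
        g21 = f02 * f10 - f00 * f12
        g22 = f00 * f11 - f01 * f10

        # (F C)_il
        fc00 = f00 * c00 + f01 * c01 + f02 * c02
        fc01 = f00 * c01 + f01 * c11 + f02 * c12
        fc02 = f00 * c02 + f01 * c12 + f02 * c22
        fc10 = f10 * c00 + f11 * c01 + f12 * c02
        fc11 = f10 * c01 + f11 * c11 + f12 * c12
        fc12 = f10 * c02 + f11 * c12 + f12 * c22
        fc20 = f20 * c00 + f21 * c01 + f22 * c02
        fc21 = f20 * c01 + f21 * c11 + f22 * c12
        fc22 = f20 * c02 + f21 * c12 + f22 * c22

        p00 = 2.0 * c1 * f00 + c2 * g00 + 4.0 * c3 * fc00
        p01 = 2.0 * c1 * f01 + c2 * g01 + 4.0 * c3 * fc01
        p02 = 2.0 * c1 * f02 + c2 * g02 + 4.0 * c3 * fc02
        p10 = 2.0 * c1 * f10 + c2 * g10 + 4.0 * c3 * fc10
        p11 = 2.0 * c1 * f11 + c2 * g11 + 4.0 * c3 * fc11
        p12 = 2.0 * c1 * f12 + c2 * g12 + 4.0 * c3 * fc12
        p20 = 2.0 * c1 * f20 + c2 * g20 + 4.0 * c3 * fc20
        p21 = 2.0 * c1 * f21 + c2 * g21 + 4.0 * c3 * fc21
        p22 = 2.0 * c1 * f22 + c2 * g22 + 4.0 * c3 * fc22

        v = V0[t]
        # local vertex a (= columns of B rows): f^a_i = -V0 sum_l P_il B_al
        fa0x = -v * (p00 * b[0, 0] + p01 * b[0, 1] + p02 * b[0, 2])
        fa0y = -v * (p10 * b[0, 0] + p11 * b[0, 1] + p12 * b[0, 2])
        fa0z = -v * (p20 * b[0, 0] + p21 * b[0, 1] + p22 * b[0, 2])
        fa1x = -v * (p00 * b[1, 0] + p01 * b[1, 1] + p02 * b[1, 2])
        fa1y = -v * (p10 * b[1, 0] + p11 * b[1, 1] + p12 * b[1, 2])
        fa1z = -v * (p20 * b[1, 0] + p21 * b[1, 1] + p22 * b[1, 2])
        fa2x = -v * (p00 * b[2, 0] + p01 * b[2, 1] + p02 * b[2, 2])
        fa2y = -v * (p10 * b[2, 0] + p11 * b[2, 1] + p12 * b[2, 2])
        fa2z = -v * (p20 * b[2, 0] + p21 * b[2, 1] + p22 * b[2, 2])

        forces[i0, 0] += fa0x
        forces[i0, 1] += fa0y
        forces[i0, 2] += fa0z
        forces[i1, 0] += fa1x
        forces[i1, 1] += fa1y
        forces[i1, 2] += fa1z
        forces[i2, 0] += fa2x
        forces[i2, 1] += fa2y
        forces[i2, 2] += fa2z
        forces[i3, 0] -= fa0x + fa1x + fa2x
        forces[i3, 1] -= fa0y + fa1y + fa2y
        forces[i3, 2] -= fa0z + fa1z + fa2z
    return energy, -1


# ---------------------------------------------------------------------------
# D3Q19 lattice-Boltzmann (BGK, Guo forcing, half-way bounce-back walls in y)
# ---------------------------------------------------------------------------

# velocity set: rest, 6 axis, 12 diagonal
_C = np.array(
    [[0, 0, 0],
     [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
     [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
     [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
     [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1]],
    dtype=np.int64,
)
_W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)
_OPP = np.array([0, 2, 1, 4, 3, 6, 5, 8, 7, 10, 9, 12, 11, 14, 13, 16, 15, 18, 17],
                dtype=np.int64)


@njit(cache=True)
def lbm_equilibrium(rho, ux, uy, uz, feq):
    """Fill feq[19] with the D3Q19 second-order equilibrium."""
    usq = ux * ux + uy * uy + uz * uz
    for q in range(19):
        cu = _C[q, 0] * ux + _C[q, 1] * uy + _C[q, 2] * uz
        feq[q] = _W[q] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)


@njit(cache=True)
def lbm_init_shear(f, u_lo, u_hi):
    """Initialize populations to equilibrium of the analytic Couette profile
    (walls half a spacing outside rows 0 and ny-1, x-speeds u_lo and u_hi)."""
    nx, ny, nz = f.shape[0], f.shape[1], f.shape[2]
    feq = np.empty(19)
    for j in range(ny):
        yj = j + 0.5
        ux = u_lo + (u_hi - u_lo) * yj / ny
        lbm_equilibrium(1.0, ux, 0.0, 0.0, feq)
        for i in range(nx):
            for k in range(nz):
                for q in range(19):
                    f[i, j, k, q] = feq[q]


@njit(cache=True)
def lbm_step(f, fnew, force, tau, u_lo, u_hi, rho_out, u_out):
    """One BGK collision + streaming cycle.

    Periodic in x and z; half-way bounce-back at the y boundaries with wall
    x-velocities ``u_lo`` (below row 0) and ``u_hi`` (above row ny-1).
    ``force`` is the body-force density field (nx, ny, nz, 3), applied with
    the Guo scheme; the macroscopic velocity written to ``u_out`` includes
    the half-force correction.  Returns the maximum |u| (lattice units) for
    stability monitoring.
    """
    nx, ny, nz = f.shape[0], f.shape[1], f.shape[2]
    omega = 1.0 / tau
    feq = np.empty(19)
    fpost = np.empty(19)
    umax = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                rho = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for q in range(19):
                    fq = f[i, j, k, q]
                    rho += fq
                    mx += fq * _C[q, 0]
                    my += fq * _C[q, 1]
                    mz += fq * _C[q, 2]
                gx = force[i, j, k, 0]
                gy = force[i, j, k, 1]
                gz = force[i, j, k, 2]
                ux = (mx + 0.5 * gx) / rho
                uy = (my + 0.5 * gy) / rho
                uz = (mz + 0.5 * gz) / rho
                rho_out[i, j, k] = rho
                u_out[i, j, k, 0] = ux
                u_out[i, j, k, 1] = uy
                u_out[i, j, k, 2] = uz
                uu = ux * ux + uy * uy + uz * uz
                if uu > umax:
                    umax = uu
                lbm_equilibrium(rho, ux, uy, uz, feq)
                for q in range(19):
                    cu = _C[q, 0] * ux + _C[q, 1] * uy + _C[q, 2] * uz
                    cg = (_C[q, 0] * gx + _C[q, 1] * gy + _C[q, 2] * gz)
                    ug = ux * gx + uy * gy + uz * gz
                    S = _W[q] * (1.0 - 0.5 * omega) * (
                        3.0 * cg + 9.0 * cu * cg - 3.0 * ug)
                    fpost[q] = (f[i, j, k, q]
                                - omega * (f[i, j, k, q] - feq[q]) + S)
                # streaming with bounce-back in y
                for q in range(19):
                    jt = j + _C[q, 1]
                    if jt < 0:
                        qo = _OPP[q]
                        corr = 6.0 * _W[q] * rho * (_C[q, 0] * u_lo)
                        fnew[i, j, k, qo] = fpost[q] - corr
                    elif jt >= ny:
                        qo = _OPP[q]
                        corr = 6.0 * _W[q] * rho * (_C[q, 0] * u_hi)
                        fnew[i, j, k, qo] = fpost[q] - corr
                    else:
                        it = i + _C[q, 0]
                        if it < 0:
                            it += nx
                        elif it >= nx:
                            it -= nx
                        kt = k + _C[q, 2]
                        if kt < 0:
                            kt += nz
                        elif kt >= nz:
                            kt -= nz
                        fnew[it, jt, kt, q] = fpost[q]
    return np.sqrt(umax)


# ---------------------------------------------------------------------------
# immersed boundary: 4-point Peskin kernel
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _peskin4(r):
    r = abs(r)
    if r < 1.0:
        return 0.125 * (3.0 - 2.0 * r + np.sqrt(1.0 + 4.0 * r - 4.0 * r * r))
    if r < 2.0:
        return 0.125 * (5.0 - 2.0 * r - np.sqrt(-7.0 + 12.0 * r - 4.0 * r * r))
    return 0.0


@njit(cache=True)
def ibm_interpolate(u_field, pos, out):
    """Interpolate lattice velocities to Lagrangian points.

    ``pos`` is in lattice coordinates (node q sits at q + 0.5 in each
    direction); x and z wrap periodically, y clamps the stencil at the walls.
    """
    nx, ny, nz = u_field.shape[0], u_field.shape[1], u_field.shape[2]
    n = pos.shape[0]
    for p in range(n):
        px = pos[p, 0] - 0.5
        py = pos[p, 1] - 0.5
        pz = pos[p, 2] - 0.5
        i0 = int(np.floor(px)) - 1
        j0 = int(np.floor(py)) - 1
        k0 = int(np.floor(pz)) - 1
        vx = 0.0
        vy = 0.0
        vz = 0.0
        for a in range(4):
            i = i0 + a
            wx = _peskin4(px - i)
            if wx == 0.0:
                continue
            ii = i % nx
            for b in range(4):
                j = j0 + b
                if j < 0 or j >= ny:
                    continue
                wy = _peskin4(py - j)
                if wy == 0.0:
                    continue
                for c in range(4):
                    kx = k0 + c
                    wz = _peskin4(pz - kx)
                    if wz == 0.0:
                        continue
                    kk = kx % nz
                    wgt = wx * wy * wz
                    vx += wgt * u_field[ii, j, kk, 0]
                    vy += wgt * u_field[ii, j, kk, 1]
                    vz += wgt * u_field[ii, j, kk, 2]
        out[p, 0] = vx
        out[p, 1] = vy
        out[p, 2] = vz


@njit(cache=True)
def ibm_spread(forces, pos, force_field):
    """Spread Lagrangian point forces onto the lattice force-density field
    (same kernel as interpolation; ``force_field`` must be zeroed)."""
    nx, ny, nz = force_field.shape[0], force_field.shape[1], force_field.shape[2]
    n = pos.shape[0]
    for p in range(n):
        px = pos[p, 0] - 0.5
        py = pos[p, 1] - 0.5
        pz = pos[p, 2] - 0.5
        i0 = int(np.floor(px)) - 1
        j0 = int(np.floor(py)) - 1
        k0 = int(np.floor(pz)) - 1
        fx = forces[p, 0]
        fy = forces[p, 1]
        fz = forces[p, 2]
        for a in range(4):
            i = i0 + a
            wx = _peskin4(px - i)
            if wx == 0.0:
                continue
            ii = i % nx
            for b in range(4):
                j = j0 + b
                if j < 0 or j >= ny:
                    continue
                wy = _peskin4(py - j)
                if wy == 0.0:
                    continue
                for c in range(4):
                    kx = k0 + c
                    wz = _peskin4(pz - kx)
                    if wz == 0.0:
                        continue
                    kk = kx % nz
                    wgt = wx * wy * wz
                    force_field[ii, j, kk, 0] += wgt * fx
                    force_field[ii, j, kk, 1] += wgt * fy
                    force_field[ii, j, kk, 2] += wgt * fz


# ---------------------------------------------------------------------------
# FIRE relaxation with penalty contact (quasi-static equilibria)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _contact_forces_inline(pos, mode, y_lo, upper, sphere_r, cx, cz, k_c,
                           forces):
    """Add penalty contact forces; returns the normal force on the moving
    boundary (upper plate or probe sphere)."""
    n = pos.shape[0]
    fmove = 0.0
    for i in range(n):
        d_lo = y_lo - pos[i, 1]
        if d_lo > 0.0:
            forces[i, 1] += k_c * d_lo
        if mode == 0:
            d_up = pos[i, 1] - upper
            if d_up > 0.0:
                forces[i, 1] -= k_c * d_up
                fmove += k_c * d_up
        else:
            dx = pos[i, 0] - cx
            dy = pos[i, 1] - upper
            dz = pos[i, 2] - cz
            dist = np.sqrt(dx * dx + dy * dy + dz * dz)
            if dist < sphere_r and dist > 1e-12:
                delta = sphere_r - dist
                forces[i, 0] += k_c * delta * dx / dist
                forces[i, 1] += k_c * delta * dy / dist
                forces[i, 2] += k_c * delta * dz / dist
                fmove += k_c * delta * (-dy / dist)
    return fmove


@njit(cache=True)
def relax_fire(tets, B, V0, verts, u, mu1, mu2, kappa,
               mode, y_lo, upper, sphere_r, cx, cz, k_c,
               tol, max_steps):
    """FIRE (fast inertial relaxation engine) pseudo-dynamics to quasi-static
    equilibrium of elastic + contact forces.

    Modifies ``u`` in place; returns (residual, fmove, iterations, status)
    with status 0 = converged, 1 = iteration cap reached, 2 = persistent
    element inversion.  Deterministic for fixed inputs.
    """
    n = u.shape[0]
    v = np.zeros((n, 3))
    forces = np.zeros((n, 3))
    pos = np.empty((n, 3))
    u_prev = u.copy()
    u_good = u.copy()
    dt = 0.01
    dt_max = 0.05
    dt_min = 1e-6
    dt_last = dt
    alpha = 0.1
    n_pos = 0
    residual = 1e300
    fmove = 0.0
    inv_streak = 0
    for it in range(max_steps):
        forces[:] = 0.0
        _, bad = elastic_force_energy(tets, B, V0, u, mu1, mu2, kappa, forces)
        if bad >= 0:
            # revert to the last state that evaluated cleanly and calm the
            # dynamics durably
            u[:] = u_good
            v[:] = 0.0
            dt = max(0.25 * dt, dt_min)
            dt_max = max(0.7 * dt_max, 10.0 * dt_min)
            n_pos = 0
            alpha = 0.1
            inv_streak += 1
            if inv_streak > 200:
                return residual, fmove, it + 1, 2
            continue
        inv_streak = 0
        u_good[:] = u
        for i in range(n):
            pos[i, 0] = verts[i, 0] + u[i, 0]
            pos[i, 1] = verts[i, 1] + u[i, 1]
            pos[i, 2] = verts[i, 2] + u[i, 2]
        fmove = _contact_forces_inline(pos, mode, y_lo, upper, sphere_r,
                                       cx, cz, k_c, forces)
        res = 0.0
        for i in range(n):
            for a in range(3):
                fa = abs(forces[i, a])
                if fa > res:
                    res = fa
        residual = res
        if res <= tol:
            return residual, fmove, it + 1, 0
        # FIRE 2.0: check power with the velocity that produced this state
        p = 0.0
        for i in range(n):
            for a in range(3):
                p += v[i, a] * forces[i, a]
        if p > 0.0:
            n_pos += 1
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        elif it > 0:
            # uphill: retract half of the step that got us here, freeze
            for i in range(n):
                for a in range(3):
                    u[i, a] -= 0.5 * dt_last * v[i, a]
            v[:] = 0.0
            dt = max(dt * 0.5, dt_min)
            alpha = 0.1
            n_pos = 0
        # semi-implicit Euler with velocity mixing
        vnorm = 0.0
        fnorm = 0.0
        for i in range(n):
            for a in range(3):
                v[i, a] += dt * forces[i, a]
                vnorm += v[i, a] * v[i, a]
                fnorm += forces[i, a] * forces[i, a]
        vnorm = np.sqrt(vnorm)
        fnorm = np.sqrt(fnorm)
        if fnorm > 0.0:
            mix = alpha * vnorm / fnorm
            for i in range(n):
                for a in range(3):
                    v[i, a] = (1.0 - alpha) * v[i, a] + mix * forces[i, a]
        u_prev[:] = u
        dt_last = dt
        for i in range(n):
            for a in range(3):
                u[i, a] += dt * v[i, a]
    return residual, fmove, max_steps, 1
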