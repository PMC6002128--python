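"""Numba-compiled inner loops for the agent-based and PDE solvers.

Everything here is plumbing for speed: the model content (equations,
parameters, schemes) is defined in :mod:`hybrid` and :mod:`pde`, which
pass plain arrays in.  All kernels are sequential and draw from numba's
global NumPy RNG state, seeded once per realization via :func:`seed_rng`,
so runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@nb.njit(cache=True, inline="always")
def _interp_u(y, x0, inv_dx, x):
    """Linear interpolation on a uniform grid, clamped at the ends."""
    t = (x - x0) * inv_dx
    if t <= 0.0:
        return y[0]
    n = y.shape[0]
    if t >= n - 1:
        return y[n - 1]
    i = int(t)
    w = t - i
    return y[i] * (1.0 - w) + y[i + 1] * w


@nb.njit(cache=True, inline="always")
def _interp2_u(tab, m0, inv_dm, z0, inv_dz, m, z):
    """Bilinear interpolation on a uniform (m, z) grid, clamped."""
    nm, nz = tab.shape
    tm = (m - m0) * inv_dm
    tz = (z - z0) * inv_dz
    if tm < 0.0:
        tm = 0.0
    if tm > nm - 1:
        tm = nm - 1.0
    if tz < 0.0:
        tz = 0.0
    if tz > nz - 1:
        tz = nz - 1.0
    i = min(int(tm), nm - 2)
    j = min(int(tz), nz - 2)
    u = tm - i
    v = tz - j
    return (tab[i, j] * (1 - u) * (1 - v) + tab[i + 1, j] * u * (1 - v)
            + tab[i, j + 1] * (1 - u) * v + tab[i + 1, j + 1] * u * v)


@nb.njit(cache=True, inline="always")
def _whole_cell_rates(Yp, a1, b1, a2, b2, c, nf, w, chooses):
    """Flagellar-voting turning rates (lam, mu) at a given CheYp."""
    lam_f = a1 * np.exp(b1 * Yp)
    mu_f = a2 * np.exp(-((b2 - Yp) ** 4) / c)
    p = mu_f / (lam_f + mu_f)
    q = 1.0 - p
    # binomial pmf terms and upper tail
    P_w = chooses[w] * p ** w * q ** (nf - w)
    P_wm1 = chooses[w - 1] * p ** (w - 1) * q ** (nf - w + 1)
    P_run = 0.0
    for i in range(w, nf + 1):
        P_run += chooses[i] * p ** i * q ** (nf - i)
    if P_run >= 1.0:
        P_run = 1.0 - 1e-15
    if P_run <= 0.0:
        P_run = 1e-300
    lam = w * lam_f * P_w / P_run
    mu = (nf - w + 1) * mu_f * P_wm1 / (1.0 - P_run)
    return lam, mu


@nb.njit(cache=True)
def refresh_internal(x, z, m, lam, mu, h, n, ncell,
                     xlo, inv_dxf, dt, r, Zw, h0,
                     mstar_tab, f_tab, yp_tab, z0g, inv_dzg, m0g, inv_dmg,
                     a1, b1, a2, b2, c, nf, w, chooses, freeze_m,
                     ms_w, lam_w, mu_w):
    """Advance (z, m) of every cell by one internal step of size dt and
    refresh the whole-cell turning rates from the (m, z) lookup tables.

    The explicit m-step is kept monotone by clamping at the quasi-steady
    level m*(z): a step may approach but never overshoot it.  Cells
    sitting exactly at the unsuppressed fixed point (z = Zw, m = m*(Zw))
    take a precomputed fast path (ms_w, lam_w, mu_w).
    """
    for i in range(ncell):
        hi = _interp_u(h, xlo, inv_dxf, x[i])
        zi = z[i]
        if hi < h0 and zi == Zw and (freeze_m or m[i] == ms_w):
            # at the fixed point: state and rates unchanged
            lam[i] = lam_w
            mu[i] = mu_w
            continue
        ni = _interp_u(n, xlo, inv_dxf, x[i])
        kV = r * ni
        if hi >= h0:
            zi += dt * (-kV * zi)
        else:
            zi += dt * (kV * (Zw - zi))
        if zi < 0.0:
            zi = 0.0
        z[i] = zi
        mi = m[i]
        if not freeze_m:
            fi = _interp2_u(f_tab, m0g, inv_dmg, z0g, inv_dzg, mi, zi)
            mnew = mi + dt * fi
            ms = _interp_u(mstar_tab, z0g, inv_dzg, zi)
            if (mi - ms) * (mnew - ms) < 0.0:
                mnew = ms
            mi = mnew
            m[i] = mi
        Yp = _interp2_u(yp_tab, m0g, inv_dmg, z0g, inv_dzg, mi, zi)
        lam[i], mu[i] = _whole_cell_rates(Yp, a1, b1, a2, b2, c,
                                          nf, w, chooses)


@nb.njit(cache=True)
def fixed_point_rates(Zw, freeze_m, m_fixed,
                      mstar_tab, yp_tab, z0g, inv_dzg, m0g, inv_dmg,
                      a1, b1, a2, b2, c, nf, w, chooses):
    """(m*, lam, mu) at the unsuppressed fixed point z = Zw, computed
    through the same interpolators as the per-cell path so the fast-path
    equality test in :func:`refresh_internal` is exact."""
    ms_w = m_fixed if freeze_m else _interp_u(mstar_tab, z0g, inv_dzg, Zw)
    Yp = _interp2_u(yp_tab, m0g, inv_dmg, z0g, inv_dzg, ms_w, Zw)
    lam_w, mu_w = _whole_cell_rates(Yp, a1, b1, a2, b2, c, nf, w, chooses)
    return ms_w, lam_w, mu_w


@nb.njit(cache=True)
def motion_steps(x, heading, moving, lam, mu, ncell, T, s0, xlo, xhi):
    """Exact velocity-jump motion over an interval T with frozen rates.

    Waiting times in the run and tumble states are sampled from their
    exponential distributions and events processed in order, so the
    scheme is unbiased for any T.  A tumble→run transition resamples the
    1D heading uniformly from {−1, +1}; runs displace ballistically at
    speed s0 and reflect at the domain walls.
    """
    for i in range(ncell):
        li = lam[i]
        mi = mu[i]
        xi = x[i]
        hd = heading[i]
        mv = moving[i]
        t_rem = T
        while t_rem > 0.0:
            if mv == 1:
                tau = -np.log(np.random.random()) / li if li > 0.0 else T * 2.0
                seg = tau if tau < t_rem else t_rem
                xi += s0 * hd * seg
                # reflecting walls (repeat in case of long ballistic legs)
                while xi > xhi or xi < xlo:
                    if xi > xhi:
                        xi = 2.0 * xhi - xi
                    else:
                        xi = 2.0 * xlo - xi
                    hd = -hd
                if tau >= t_rem:
                    break
                mv = 0
                t_rem -= tau
            else:
                tau = -np.log(np.random.random()) / mi if mi > 0.0 else T * 2.0
                if tau >= t_rem:
                    break
                mv = 1
                hd = 1.0 if np.random.random() < 0.5 else -1.0
                t_rem -= tau
        x[i] = xi
        heading[i] = hd
        moving[i] = mv
    return


@nb.njit(cache=True, inline="always")
def _new_heading(vel, dim):
    if dim == 1:
        vel[0] = 1.0 if np.random.random() < 0.5 else -1.0
    elif dim == 2:
        th = 2.0 * np.pi * np.random.random()
        vel[0], vel[1] = np.cos(th), np.sin(th)
    else:
        u = 2.0 * np.random.random() - 1.0
        th = 2.0 * np.pi * np.random.random()
        s = np.sqrt(1.0 - u * u)
        vel[0], vel[1], vel[2] = s * np.cos(th), s * np.sin(th), u


@nb.njit(cache=True)
def walk_msd(n_agents, lam, mu, s0, T_rec, nrec, dim, seed):
    """Exact velocity-jump walk with frozen rates in 1, 2 or 3 dimensions
    on an unbounded domain; returns the mean squared displacement at times
    T_rec, 2·T_rec, ..., nrec·T_rec.

    Independent oracle-style simulator used to validate the effective
    diffusion coefficient; kept separate from the colony simulator.
    """
    np.random.seed(seed)
    msd = np.zeros(nrec)
    p_run0 = mu / (lam + mu)
    for a in range(n_agents):
        pos = np.zeros(dim)
        vel = np.zeros(dim)
        moving = np.random.random() < p_run0
        _new_heading(vel, dim)
        for k in range(nrec):
            t_rem = T_rec
            while t_rem > 0.0:
                if moving:
                    tau = -np.log(np.random.random()) / lam
                    seg = tau if tau < t_rem else t_rem
                    for d in range(dim):
                        pos[d] += s0 * vel[d] * seg
                    if tau >= t_rem:
                        break
                    moving = False
                    t_rem -= tau
                else:
                    tau = -np.log(np.random.random()) / mu
                    if tau >= t_rem:
                        break
                    moving = True
                    _new_heading(vel, dim)
                    t_rem -= tau
            r2 = 0.0
            for d in range(dim):
                r2 += pos[d] * pos[d]
            msd[k] += r2
    return msd / n_agents


@nb.njit(cache=True)
def thomas_factor(aW, aE):
    """Prefactorized forward-elimination coefficients for the tridiagonal
    system (1 + aW + aE) on the diagonal, −aW/−aE off-diagonal."""
    n = aW.shape[0]
    cp = np.empty(n)
    denom = np.empty(n)
    b0 = 1.0 + aW[0] + aE[0]
    denom[0] = b0
    cp[0] = -aE[0] / b0
    for i in range(1, n):
        b = 1.0 + aW[i] + aE[i]
        denom[i] = b + aW[i] * cp[i - 1]
        cp[i] = -aE[i] / denom[i]
    return cp, denom


@nb.njit(cache=True)
def thomas_solve_pref(cp, denom, aW, rhs, out):
    """Back-substitution using prefactorized coefficients."""
    n = rhs.shape[0]
    out[0] = rhs[0] / denom[0]
    for i in range(1, n):
        out[i] = (rhs[i] + aW[i] * out[i - 1]) / denom[i]
    for i in range(n - 2, -1, -1):
        out[i] = out[i] - cp[i] * out[i + 1]


@nb.njit(cache=True)
def pde_step(rho, h, n, Dcoef_W, Dcoef_E, cp_rho, den_rho,
             cp_h, den_h, aW_h, cp_n, den_n, aW_n,
             z_faces, dz, dt, r, kappa, Zw, h0, alpha, beta, gamma,
             work, rho_marg):
    """One IMEX step of the internal-state density model.

    rho has shape (Nz, Nx).  Sequence: explicit conservative upwind
    advection in z with velocity kappa·g(z, h(x)); exact exponential
    growth factor; implicit spatial diffusion per z-level (prefactorized
    Thomas); AHL/nutrient update (implicit diffusion, exact decay /
    consumption factors, source from the current density marginal).
    """
    Nz, Nx = rho.shape
    # --- z-advection (explicit upwind, zero flux at z-boundaries)
    for i in range(Nx):
        kV = kappa * r * n[i]
        suppressed = h[i] >= h0
        # fluxes at interior z-faces
        Fprev = 0.0
        for j in range(Nz):
            if j < Nz - 1:
                zf = z_faces[j + 1]
                v = -kV * zf if suppressed else kV * (Zw - zf)
                F = v * rho[j, i] if v > 0.0 else v * rho[j + 1, i]
            else:
                F = 0.0
            work[j] = (F - Fprev) / dz
            Fprev = F
        for j in range(Nz):
            rho[j, i] -= dt * work[j]
    # --- growth (exact per-step exponential)
    for i in range(Nx):
        gfac = np.exp(r * n[i] * dt)
        for j in range(Nz):
            rho[j, i] *= gfac
    # --- spatial diffusion, implicit per z-level
    out = np.empty(Nx)
    for j in range(Nz):
        thomas_solve_pref(cp_rho[j], den_rho[j], Dcoef_W[j], rho[j], out)
        for i in range(Nx):
            rho[j, i] = out[i]
    # --- marginal density
    for i in range(Nx):
        s = 0.0
        for j in range(Nz):
            s += rho[j, i]
        rho_marg[i] = s * dz
    # --- fields: implicit diffusion then exact reaction factors
    thomas_solve_pref(cp_h, den_h, aW_h, h, out)
    Eb = np.exp(-beta * dt)
    src = (1.0 - Eb) / beta
    for i in range(Nx):
        h[i] = out[i] * Eb + alpha * rho_marg[i] * src
    thomas_solve_pref(cp_n, den_n, aW_n, n, out)
    for i in range(Nx):
        n[i] = out[i] * np.exp(-gamma * rho_marg[i] * dt)


@nb.njit(cache=True)
def reduced_step(rho, h, n, Dbar, aW, aE, cp_h, den_h, aW_h,
                 cp_n, den_n, aW_n, dt, r, D_lo, D_hi, h0,
                 alpha, beta, gamma):
    """One step of the scalar switch-diffusivity model.

    The cell flux is ∇(D̄(h)ρ) with D̄ a step function of AHL (D_hi below
    the threshold, D_lo above), solved implicitly; growth and the fields
    are handled as in :func:`pde_step`.
    """
    Nx = rho.shape[0]
    for i in range(Nx):
        Dbar[i] = D_lo if h[i] >= h0 else D_hi
        rho[i] *= np.exp(r * n[i] * dt)
    # implicit solve of (V - dt*L*diag(Dbar)) rho_new = V rho
    # tridiagonal: -aW_i*Dbar[i-1]*x[i-1] + (1+ (aW_i+aE_i)*Dbar[i])*x[i]
    #              -aE_i*Dbar[i+1]*x[i+1] = rho[i]
    lo = np.empty(Nx)
    di = np.empty(Nx)
    up = np.empty(Nx)
    for i in range(Nx):
        lo[i] = -aW[i] * (Dbar[i - 1] if i > 0 else 0.0)
        di[i] = 1.0 + (aW[i] + aE[i]) * Dbar[i]
        up[i] = -aE[i] * (Dbar[i + 1] if i < Nx - 1 else 0.0)
    # generic Thomas
    cp = np.empty(Nx)
    xp = np.empty(Nx)
    cp[0] = up[0] / di[0]
    xp[0] = rho[0] / di[0]
    for i in range(1, Nx):
        mden = di[i] - lo[i] * cp[i - 1]
        cp[i] = up[i] / mden
        xp[i] = (rho[i] - lo[i] * xp[i - 1]) / mden
    rho[Nx - 1] = xp[Nx - 1]
    for i in range(Nx - 2, -1, -1):
        rho[i] = xp[i] - cp[i] * rho[i + 1]
    out = np.empty(Nx)
    thomas_solve_pref(cp_h, den_h, aW_h, h, out)
    Eb = np.exp(-beta * dt)
    src = (1.0 - Eb) / beta
    for i in range(Nx):
        h[i] = out[i] * Eb + alpha * rho[i] * src
    thomas_solve_pref(cp_n, den_n, aW_n, n, out)
    for i in range(Nx):
        n[i] = out[i] * np.exp(-gamma * rho[i] * dt)
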