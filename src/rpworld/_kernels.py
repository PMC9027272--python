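"""Numba-compiled inner loops for the lattice and agent simulators.

Every kernel has a pure-NumPy twin in the public modules; the lattice
kernel reproduces the NumPy update bit-for-bit (same operation order),
which the test suite checks.  If numba is unavailable the package falls
back to the NumPy paths.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(fastmath=False)
def pde_step_kernel(r, p, a, n, r2, p2, a2, n2, normals, use_noise,
                    aR, dR, dP, m, n0, D, Dn, sigma_a, dt,
                    a_min, a_max, p_floor, moore):
    """One forward-Euler lattice step; writes into r2/p2/a2/n2.

    Operation order matches the vectorized NumPy implementation exactly
    so the two backends are bit-identical.  Returns per-field totals
    (sum r2, sum p2, sum n2, sum a2*p2) for cheap per-step summaries.
    """
    nx, ny = r.shape
    c_rep = aR * dt
    one_m = 1.0 - m
    Ddt = D * dt
    Dndt = Dn * dt
    dRdt = dR * dt
    dPdt = dP * dt
    n0dt = n0 * dt
    s0 = sigma_a * np.sqrt(dt)
    tot_r = 0.0
    tot_p = 0.0
    tot_n = 0.0
    tot_ap = 0.0
    for i in range(nx):
        im1 = i - 1 if i > 0 else nx - 1
        ip1 = i + 1 if i < nx - 1 else 0
        for j in range(ny):
            jm1 = j - 1 if j > 0 else ny - 1
            jp1 = j + 1 if j < ny - 1 else 0
            ri = r[i, j]
            pi = p[i, j]
            ai = a[i, j]
            ni = n[i, j]
            new_r = c_rep * ri * ri * one_m * ni
            new_p = dt * ri * (aR * ri * m + ai * pi) * ni
            used = new_r + new_p
            if used > ni:
                scale = ni / used
                new_r = new_r * scale
                new_p = new_p * scale
            if moore:
                avg_r = (r[im1, j] + r[ip1, j] + r[i, jm1] + r[i, jp1]
                         + r[im1, jm1] + r[im1, jp1]
                         + r[ip1, jm1] + r[ip1, jp1]) * 0.125
                avg_p = (p[im1, j] + p[ip1, j] + p[i, jm1] + p[i, jp1]
                         + p[im1, jm1] + p[im1, jp1]
                         + p[ip1, jm1] + p[ip1, jp1]) * 0.125
                avg_n = (n[im1, j] + n[ip1, j] + n[i, jm1] + n[i, jp1]
                         + n[im1, jm1] + n[im1, jp1]
                         + n[ip1, jm1] + n[ip1, jp1]) * 0.125
                avg_ap = (a[im1, j] * p[im1, j] + a[ip1, j] * p[ip1, j]
                          + a[i, jm1] * p[i, jm1] + a[i, jp1] * p[i, jp1]
                          + a[im1, jm1] * p[im1, jm1]
                          + a[im1, jp1] * p[im1, jp1]
                          + a[ip1, jm1] * p[ip1, jm1]
                          + a[ip1, jp1] * p[ip1, jp1]) * 0.125
            else:
                avg_r = (r[im1, j] + r[ip1, j]
                         + r[i, jm1] + r[i, jp1]) * 0.25
                avg_p = (p[im1, j] + p[ip1, j]
                         + p[i, jm1] + p[i, jp1]) * 0.25
                avg_n = (n[im1, j] + n[ip1, j]
                         + n[i, jm1] + n[i, jp1]) * 0.25
                avg_ap = (a[im1, j] * p[im1, j] + a[ip1, j] * p[ip1, j]
                          + a[i, jm1] * p[i, jm1]
                          + a[i, jp1] * p[i, jp1]) * 0.25
            ap = ai * pi
            rv = ri + new_r - dRdt * ri + Ddt * (avg_r - ri)
            pv = pi + new_p - dPdt * pi + Ddt * (avg_p - pi)
            new_ap = ap + Ddt * (avg_ap - ap)
            p_diff = pi + Ddt * (avg_p - pi)
            if p_diff > 0.0:
                av = new_ap / p_diff
            else:
                av = ai
            nv = ni + n0dt - new_r - new_p + Dndt * (avg_n - ni)
            if use_noise:
                pf = pi if pi > p_floor else p_floor
                av = av + (s0 / np.sqrt(pf)) * normals[i, j]
            if rv < 0.0:
                rv = 0.0
            if pv < 0.0:
                pv = 0.0
            if nv < 0.0:
                nv = 0.0
            if av < a_min:
                av = a_min
            elif av > a_max:
                av = a_max
            r2[i, j] = rv
            p2[i, j] = pv
            a2[i, j] = av
            n2[i, j] = nv
            tot_r += rv
            tot_p += pv
            tot_n += nv
            tot_ap += av * pv
    return tot_r, tot_p, tot_n, tot_ap


# --------------------------------------------------------------------------
# Well-mixed ODE and pendulum RK4 loops
# --------------------------------------------------------------------------

@njit(fastmath=False)
def well_mixed_kernel(out, aR, aP, dR, dP, m, n0, dt, clamp_p):
    """Fixed-step RK4 for the homogeneous (n, r, p) system.

    ``out`` is (n_steps+1, 3) with row 0 pre-filled; negative
    components are clamped to 0 after every step.
    """
    n_steps = out.shape[0] - 1
    n = out[0, 0]
    r = out[0, 1]
    p = out[0, 2]
    one_m = 1.0 - m
    for k in range(1, n_steps + 1):
        k1n, k1r, k1p = _wm_rhs(n, r, p, aR, aP, dR, dP, one_m, n0, clamp_p)
        h = 0.5 * dt
        k2n, k2r, k2p = _wm_rhs(n + h * k1n, r + h * k1r, p + h * k1p,
                                aR, aP, dR, dP, one_m, n0, clamp_p)
        k3n, k3r, k3p = _wm_rhs(n + h * k2n, r + h * k2r, p + h * k2p,
                                aR, aP, dR, dP, one_m, n0, clamp_p)
        k4n, k4r, k4p = _wm_rhs(n + dt * k3n, r + dt * k3r, p + dt * k3p,
                                aR, aP, dR, dP, one_m, n0, clamp_p)
        n += dt / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
        r += dt / 6.0 * (k1r + 2.0 * k2r + 2.0 * k3r + k4r)
        p += dt / 6.0 * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
        if n < 0.0:
            n = 0.0
        if r < 0.0:
            r = 0.0
        if p < 0.0:
            p = 0.0
        out[k, 0] = n
        out[k, 1] = r
        out[k, 2] = p


@njit(fastmath=False)
def _wm_rhs(n, r, p, aR, aP, dR, dP, one_m, n0, clamp_p):
    dn = n0 - n * r * (aR * r + aP * p)
    dr = one_m * aR * n * r * r - dR * r
    if clamp_p:
        dp = 0.0
    else:
        dp = (1.0 - one_m) * aR * n * r * r + aP * n * r * p - dP * p
    return dn, dr, dp


@njit(fastmath=False)
def pendulum_kernel(ts, ys, vs, c0, dRaR, dR, app, aR, dt, cap):
    """RK4 for y'' = P(y) + Q(y) y' with
    P(y) = c0 + dRaR/y, Q(y) = dR - app/y - aR/y**2.

    Truncates when y leaves (0, cap); returns (last index, diverged).
    """
    n_steps = ts.shape[0] - 1
    y = ys[0]
    v = vs[0]
    for k in range(1, n_steps + 1):
        k1y = v
        k1v = (c0 + dRaR / y) + (dR - app / y - aR / (y * y)) * v
        y2 = y + 0.5 * dt * k1y
        v2 = v + 0.5 * dt * k1v
        k2y = v2
        k2v = (c0 + dRaR / y2) + (dR - app / y2 - aR / (y2 * y2)) * v2
        y3 = y + 0.5 * dt * k2y
        v3 = v + 0.5 * dt * k2v
        k3y = v3
        k3v = (c0 + dRaR / y3) + (dR - app / y3 - aR / (y3 * y3)) * v3
        y4 = y + dt * k3y
        v4 = v + dt * k3v
        k4y = v4
        k4v = (c0 + dRaR / y4) + (dR - app / y4 - aR / (y4 * y4)) * v4
        y = y + dt / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
        v = v + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        ts[k] = k * dt
        ys[k] = y
        vs[k] = v
        if not (0.0 < y < cap) or not np.isfinite(y):
            return k, True
    return n_steps, False


# --------------------------------------------------------------------------
# Agent-model engine
# --------------------------------------------------------------------------

@njit
def seed_rng(seed):
    np.random.seed(seed)


@njit
def _cell_of(v, inv_cell, ncell):
    c = int(v * inv_cell)
    if c >= ncell:
        c = ncell - 1
    if c < 0:
        c = 0
    return c


@njit
def _bin_add(bins, bin_count, cell, idx):
    cnt = bin_count[cell]
    if cnt >= bins.shape[1]:
        return False
    bins[cell, cnt] = idx
    bin_count[cell] = cnt + 1
    return True


@njit
def _bin_remove(bins, bin_count, cell, idx):
    cnt = bin_count[cell]
    for k in range(cnt):
        if bins[cell, k] == idx:
            bins[cell, k] = bins[cell, cnt - 1]
            bin_count[cell] = cnt - 1
            return


@njit
def mas_run_kernel(x, y, rep, kp, rlt, alive, n_init,
                   sizeX, sizeY, radius, Nmax, d, kR, dt, D, delta, mP,
                   time_limit,
                   out_nr, out_np, out_kp_mean, out_kp_min, out_kp_max):
    """Full agent-simulation loop (Brownian moves, overlap reactions,
    RLT decay, crowding death, kP mutation).

    The caller seeds the RNG and pre-fills agents [0, n_init).  Output
    arrays are filled per recorded step; returns (n_records, n_total,
    status) with status 0 = ok, 1 = agent capacity exceeded, 2 = cell
    capacity exceeded.
    """
    cap = x.shape[0]
    r2 = radius * radius
    step_sd = np.sqrt(2.0 * D * dt)
    ddt = d * dt
    half = delta * 0.5
    # cell size >= interaction radius so +-1 cells cover every neighbour
    ncx = max(1, int(sizeX / radius))
    ncy = max(1, int(sizeY / radius))
    inv_cx = ncx / sizeX
    inv_cy = ncy / sizeY
    bins = np.empty((ncx * ncy, 128), dtype=np.int32)
    bin_count = np.zeros(ncx * ncy, dtype=np.int32)
    cell_x = np.empty(cap, dtype=np.int32)
    cell_y = np.empty(cap, dtype=np.int32)
    nb = np.empty(4096, dtype=np.int32)
    xcells = np.empty(3, dtype=np.int64)
    ycells = np.empty(3, dtype=np.int64)

    n_tot = n_init

    # record initial state
    rec = 0
    nr = 0
    npar = 0
    for i in range(n_tot):
        if alive[i]:
            if rep[i]:
                nr += 1
            else:
                npar += 1
    _record(kp, rep, alive, n_tot, nr, npar, rec,
            out_nr, out_np, out_kp_mean, out_kp_min, out_kp_max)
    rec += 1

    for _step in range(1, time_limit + 1):
        if nr == 0 or npar == 0:
            break
        # 1. RLT decay: decrement, remove at zero
        for i in range(n_tot):
            if alive[i]:
                rlt[i] -= 1
                if rlt[i] <= 0:
                    alive[i] = 0
        # 2. compact live agents to the front
        n = 0
        for i in range(n_tot):
            if alive[i]:
                if n != i:
                    x[n] = x[i]
                    y[n] = y[i]
                    rep[n] = rep[i]
                    kp[n] = kp[i]
                    rlt[n] = rlt[i]
                alive[n] = 1
                n += 1
        n_tot = n
        # 3. rebuild spatial bins
        for c in range(ncx * ncy):
            bin_count[c] = 0
        for i in range(n_tot):
            cx = _cell_of(x[i], inv_cx, ncx)
            cy = _cell_of(y[i], inv_cy, ncy)
            cell_x[i] = cx
            cell_y[i] = cy
            if not _bin_add(bins, bin_count, cx * ncy + cy, i):
                return rec, n_tot, 2
        # 4. randomized processing order (fixed for this step; agents
        #    born during the step do not act until the next one)
        order = np.arange(n_tot)
        np.random.shuffle(order)
        for oi in range(n_tot):
            i = order[oi]
            if not alive[i]:
                continue
            # neighbours: overlap means centre distance < 2*agent_size
            ncand_x = _wrap_cells(cell_x[i], ncx, xcells)
            ncand_y = _wrap_cells(cell_y[i], ncy, ycells)
            cnt = 0
            for a_ in range(ncand_x):
                for b_ in range(ncand_y):
                    c = xcells[a_] * ncy + ycells[b_]
                    for k in range(bin_count[c]):
                        j = bins[c, k]
                        if j == i or not alive[j]:
                            continue
                        dx = x[j] - x[i]
                        dx -= sizeX * np.round(dx / sizeX)
                        dy = y[j] - y[i]
                        dy -= sizeY * np.round(dy / sizeY)
                        if dx * dx + dy * dy < r2:
                            if cnt < nb.shape[0]:
                                nb[cnt] = j
                                cnt += 1
            # crowding death
            if cnt > Nmax:
                alive[i] = 0
                _bin_remove(bins, bin_count,
                            cell_x[i] * ncy + cell_y[i], i)
                if rep[i]:
                    nr -= 1
                else:
                    npar -= 1
                continue
            np.random.shuffle(nb[:cnt])
            # Brownian move, periodic wrap, bin update
            xi_new = (x[i] + step_sd * np.random.normal()) % sizeX
            yi_new = (y[i] + step_sd * np.random.normal()) % sizeY
            x[i] = xi_new
            y[i] = yi_new
            cx = _cell_of(xi_new, inv_cx, ncx)
            cy = _cell_of(yi_new, inv_cy, ncy)
            if cx != cell_x[i] or cy != cell_y[i]:
                _bin_remove(bins, bin_count,
                            cell_x[i] * ncy + cell_y[i], i)
                if not _bin_add(bins, bin_count, cx * ncy + cy, i):
                    return rec, n_tot, 2
                cell_x[i] = cx
                cell_y[i] = cy
            # pairwise replication attempts
            for k in range(cnt):
                j = nb[k]
                if not alive[j]:
                    continue
                if rep[i]:
                    if rep[j]:
                        prob = kR
                        tmpl = j
                    else:
                        prob = kp[j]
                        tmpl = j
                else:
                    if rep[j]:
                        prob = kp[i]
                        tmpl = i
                    else:
                        continue  # two parasites: no reaction
                if np.random.random() < prob:
                    if n_tot >= cap:
                        return rec, n_tot, 1
                    m_ = n_tot
                    n_tot += 1
                    x[m_] = x[tmpl]
                    y[m_] = y[tmpl]
                    rep[m_] = rep[tmpl]
                    new_kp = kp[tmpl]
                    if not rep[tmpl]:
                        if np.random.random() < mP:
                            new_kp += np.random.uniform(-half, half)
                            if new_kp < 0.0:
                                new_kp = 0.0
                            elif new_kp > 1.0:
                                new_kp = 1.0
                    kp[m_] = new_kp
                    u = 1.0 - np.random.random()  # uniform on (0, 1]
                    rlt[m_] = np.int64(-np.log(u) / ddt) + 1
                    alive[m_] = 1
                    ccx = _cell_of(x[m_], inv_cx, ncx)
                    ccy = _cell_of(y[m_], inv_cy, ncy)
                    cell_x[m_] = ccx
                    cell_y[m_] = ccy
                    if not _bin_add(bins, bin_count, ccx * ncy + ccy, m_):
                        return rec, n_tot, 2
                    if rep[m_]:
                        nr += 1
                    else:
                        npar += 1
        # 5. recount (decay already subtracted lazily; recount exactly)
        nr = 0
        npar = 0
        for i in range(n_tot):
            if alive[i]:
                if rep[i]:
                    nr += 1
                else:
                    npar += 1
        _record(kp, rep, alive, n_tot, nr, npar, rec,
                out_nr, out_np, out_kp_mean, out_kp_min, out_kp_max)
        rec += 1
    return rec, n_tot, 0


@njit
def _wrap_cells(c, ncell, out):
    """Unique wrapped cell indices {c-1, c, c+1}; handles ncell < 3."""
    if ncell >= 3:
        out[0] = c - 1 if c > 0 else ncell - 1
        out[1] = c
        out[2] = c + 1 if c < ncell - 1 else 0
        return 3
    for k in range(ncell):
        out[k] = k
    return ncell


@njit
def _record(kp, rep, alive, n_tot, nr, npar, rec,
            out_nr, out_np, out_kp_mean, out_kp_min, out_kp_max):
    out_nr[rec] = nr
    out_np[rec] = npar
    if npar > 0:
        s = 0.0
        mn = 2.0
        mx = -1.0
        for i in range(n_tot):
            if alive[i] and not rep[i]:
                v = kp[i]
                s += v
                if v < mn:
                    mn = v
                if v > mx:
                    mx = v
        out_kp_mean[rec] = s / npar
        out_kp_min[rec] = mn
        out_kp_max[rec] = mx
    else:
        out_kp_mean[rec] = np.nan
        out_kp_min[rec] = np.nan
        out_kp_max[rec] = np.nan
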