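"""Numba kernels: Yukawa segment forces and greedy one-to-one matching.

Kept free of package imports so they compile once and cache cleanly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_D_CLAMP = 1e-6  # minimum segment separation; closer centres are clamped


@njit(cache=True, fastmath=True)
def _pair_accumulate(k, m, seg_x, seg_y, seg_rod, seg_s, ux, uy, L, u0, lam,
                     cutoff2, fx, fy, tau, u_acc):
    i = seg_rod[k]
    j = seg_rod[m]
    if i == j:
        return 0.0
    dx = seg_x[m] - seg_x[k]
    dy = seg_y[m] - seg_y[k]
    # minimum image
    dx -= L * np.rint(dx / L)
    dy -= L * np.rint(dy / L)
    d2 = dx * dx + dy * dy
    if d2 >= cutoff2:
        return 0.0
    d = np.sqrt(d2)
    if d < _D_CLAMP:
        d = _D_CLAMP
        d2 = d * d
    e = u0 * np.exp(-d / lam)
    # U = e/d ;  -dU/dd = e*(1/(lam*d) + 1/d^2)
    w = e * (1.0 / (lam * d) + 1.0 / d2) / d
    # force on segment k points away from m
    fkx = -w * dx
    fky = -w * dy
    fx[i] += fkx
    fy[i] += fky
    fx[j] -= fkx
    fy[j] -= fky
    # torque about each rod centre: tau = s * (u_perp . F), u_perp = (-uy, ux)
    tau[i] += seg_s[k] * (-uy[i] * fkx + ux[i] * fky)
    tau[j] += seg_s[m] * (uy[j] * fkx - ux[j] * fky)
    u_acc[0] += e / d
    return 0.0


@njit(cache=True, fastmath=True)
def yukawa_forces(seg_x, seg_y, seg_rod, seg_s, ux, uy, n_rods, L, u0, lam, cutoff):
    """Forces, torques and total potential of mutually repulsive rod segments.

    Rods are discretized into point Yukawa charges (``seg_*`` arrays, one
    entry per segment); interactions between segments of the same rod are
    skipped.  Doubly periodic domain of side ``L`` with minimum-image
    distances; pair interactions beyond ``cutoff`` are ignored.
    """
    M = seg_x.shape[0]
    fx = np.zeros(n_rods)
    fy = np.zeros(n_rods)
    tau = np.zeros(n_rods)
    u_acc = np.zeros(1)
    cutoff2 = cutoff * cutoff
    ncell = int(L // cutoff)
    if ncell < 3:
        # domain too small for a cell list: all pairs
        for k in range(M):
            for m in range(k + 1, M):
                _pair_accumulate(k, m, seg_x, seg_y, seg_rod, seg_s, ux, uy,
                                 L, u0, lam, cutoff2, fx, fy, tau, u_acc)
        return fx, fy, tau, u_acc[0]

    cell = L / ncell
    head = np.full(ncell * ncell, -1, dtype=np.int64)
    nxt = np.full(M, -1, dtype=np.int64)
    cx = np.empty(M, dtype=np.int64)
    cy = np.empty(M, dtype=np.int64)
    for k in range(M):
        a = int(seg_x[k] / cell) % ncell
        b = int(seg_y[k] / cell) % ncell
        cx[k] = a
        cy[k] = b
        c = a * ncell + b
        nxt[k] = head[c]
        head[c] = k
    for k in range(M):
        for da in range(-1, 2):
            a = (cx[k] + da) % ncell
            for db in range(-1, 2):
                b = (cy[k] + db) % ncell
                m = head[a * ncell + b]
                while m != -1:
                    if m > k:
                        _pair_accumulate(k, m, seg_x, seg_y, seg_rod, seg_s,
                                         ux, uy, L, u0, lam, cutoff2,
                                         fx, fy, tau, u_acc)
                    m = nxt[m]
    return fx, fy, tau, u_acc[0]


@njit(cache=True)
def greedy_one_to_one(src, dst, n_src, n_dst, limit):
    """Greedy mutually exclusive matching over candidates sorted by score.

    ``src``/``dst`` are row indices of candidate pairs, already sorted in the
    desired acceptance order; at most ``limit`` pairs are accepted and each
    source/destination is used once.  Returns a boolean acceptance mask.
    """
    used_src = np.zeros(n_src, dtype=np.bool_)
    used_dst = np.zeros(n_dst, dtype=np.bool_)
    accept = np.zeros(src.shape[0], dtype=np.bool_)
    taken = 0
    for k in range(src.shape[0]):
        if taken >= limit:
            break
        i = src[k]
        j = dst[k]
        if not used_src[i] and not used_dst[j]:
            used_src[i] = True
            used_dst[j] = True
            accept[k] = True
            taken += 1
    return accept


@njit(cache=True, fastmath=True)
def _velocities(r, phi, seg_rod, seg_s, f_par, f_perp, f_rot, nu, L, u0, lam,
                cutoff):
    n = r.shape[0]
    ux = np.cos(phi)
    uy = np.sin(phi)
    seg_x = np.empty(seg_rod.shape[0])
    seg_y = np.empty(seg_rod.shape[0])
    for k in range(seg_rod.shape[0]):
        i = seg_rod[k]
        seg_x[k] = (r[i, 0] + seg_s[k] * ux[i]) % L
        seg_y[k] = (r[i, 1] + seg_s[k] * uy[i]) % L
    fx, fy, tau, _ = yukawa_forces(seg_x, seg_y, seg_rod, seg_s, ux, uy, n,
                                   L, u0, lam, cutoff)
    v = np.empty((n, 2))
    w = np.empty(n)
    for i in range(n):
        gx = fx[i] + nu * ux[i]
        gy = fy[i] + nu * uy[i]
        gpar = gx * ux[i] + gy * uy[i]
        v[i, 0] = gpar / f_par[i] * ux[i] + (gx - gpar * ux[i]) / f_perp[i]
        v[i, 1] = gpar / f_par[i] * uy[i] + (gy - gpar * uy[i]) / f_perp[i]
        w[i] = tau[i] / f_rot[i]
    return v, w


@njit(cache=True, fastmath=True)
def _midpoint_inplace(r, phi, seg_rod, seg_s, f_par, f_perp, f_rot, nu, L,
                      u0, lam, cutoff, dt, max_disp):
    """One midpoint step in place; False if it exceeded the step limit."""
    v1, w1 = _velocities(r, phi, seg_rod, seg_s, f_par, f_perp, f_rot, nu, L,
                         u0, lam, cutoff)
    r_mid = r + 0.5 * dt * v1
    phi_mid = phi + 0.5 * dt * w1
    v2, w2 = _velocities(r_mid, phi_mid, seg_rod, seg_s, f_par, f_perp,
                         f_rot, nu, L, u0, lam, cutoff)
    biggest = 0.0
    for i in range(r.shape[0]):
        d = abs(dt * v2[i, 0])
        if d > biggest:
            biggest = d
        d = abs(dt * v2[i, 1])
        if d > biggest:
            biggest = d
    if biggest > max_disp:
        return False
    for i in range(r.shape[0]):
        r[i, 0] = (r[i, 0] + dt * v2[i, 0]) % L
        r[i, 1] = (r[i, 1] + dt * v2[i, 1]) % L
        phi[i] = phi[i] + dt * w2[i]
    return True


@njit(cache=True, fastmath=True)
def integrate_steps(r, phi, seg_rod, seg_s, f_par, f_perp, f_rot, nu, L, u0,
                    lam, cutoff, dt, n_steps, max_disp, max_subdiv):
    """Midpoint integration with automatic step halving.

    Advances ``n_steps`` outer steps of size ``dt`` in place; any outer step
    whose per-rod displacement would exceed ``max_disp`` is retried with
    progressively halved substeps (up to ``max_subdiv`` subdivisions).
    Returns False if the state went non-finite.
    """
    for _ in range(n_steps):
        nsub = 1
        while True:
            r_try = r.copy()
            phi_try = phi.copy()
            ok = True
            h = dt / nsub
            for _s in range(nsub):
                if not _midpoint_inplace(r_try, phi_try, seg_rod, seg_s,
                                         f_par, f_perp, f_rot, nu, L, u0,
                                         lam, cutoff, h, max_disp):
                    ok = False
                    break
            if ok or nsub >= max_subdiv:
                if not ok:
                    # accept the capped-resolution attempt: rerun ignoring cap
                    r_try = r.copy()
                    phi_try = phi.copy()
                    for _s in range(nsub):
                        _midpoint_inplace(r_try, phi_try, seg_rod, seg_s,
                                          f_par, f_perp, f_rot, nu, L, u0,
                                          lam, cutoff, h, 1e300)
                r[:] = r_try
                phi[:] = phi_try
                break
            nsub *= 2
    for i in range(r.shape[0]):
        if not (np.isfinite(r[i, 0]) and np.isfinite(r[i, 1]) and np.isfinite(phi[i])):
            return False
    return True
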