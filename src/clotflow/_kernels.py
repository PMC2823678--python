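"""Numba-accelerated inner loops for the transport/reaction integrator.

The pure-numpy implementations in :mod:`clotflow.transport` and
:mod:`clotflow.scheme` are the reference; these kernels reproduce them
bit-compatibly (same arithmetic, same step-control logic) at loop speed.
When numba is unavailable the package transparently falls back to numpy.

Reaction networks are packed into flat arrays: ``law`` codes each reaction
(0 = zero/first-order mass action, 1 = second-order mass action,
2 = Michaelis–Menten, 3 = reversible binding), ``pa/pb`` are its rate
constants, ``ia/ib/ic`` its species indices, and the net stoichiometry is
stored CSR-style in (``net_ptr``, ``net_idx``, ``net_coef``).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def eval_rates_packed(
    flat, law, pa, pb, ia, ib, ic, net_ptr, net_idx, net_coef, surf, mask, out
):
    """Net production rates for all cells; ``flat``/(out) are (n_species, n_cells)."""
    n_rx = law.shape[0]
    n_cells = flat.shape[1]
    out[:, :] = 0.0
    for r in range(n_rx):
        lw = law[r]
        for c in range(n_cells):
            if surf[r] and mask[c] == 0.0:
                continue
            if lw == 0:
                rate = pa[r] * (flat[ia[r], c] if ia[r] >= 0 else 1.0)
            elif lw == 1:
                rate = pa[r] * flat[ia[r], c] * flat[ib[r], c]
            elif lw == 2:
                s = flat[ib[r], c]
                rate = pa[r] * flat[ia[r], c] * s / (pb[r] + s)
            else:
                rate = pa[r] * flat[ia[r], c] * flat[ib[r], c] - pb[r] * flat[ic[r], c]
            for e in range(net_ptr[r], net_ptr[r + 1]):
                out[net_idx[e], c] += net_coef[e] * rate
    return out


@njit(cache=True)
def react_bs23_packed(
    flat, mask, dt, rtol, atol,
    law, pa, pb, ia, ib, ic, net_ptr, net_idx, net_coef, surf,
    clip_out,
):
    """Adaptive Bogacki–Shampine 3(2) chemistry sub-stepping, whole grid.

    Mirrors the numpy reference step control exactly: shared step size, the
    worst-cell error estimate, FSAL reuse, 0.2–5× step factor clamping, and
    non-negativity clipping with per-species mass logging into ``clip_out``.
    """
    nsp, ncell = flat.shape
    k1 = np.empty((nsp, ncell))
    k2 = np.empty((nsp, ncell))
    k3 = np.empty((nsp, ncell))
    k4 = np.empty((nsp, ncell))
    stage = np.empty((nsp, ncell))
    cand = np.empty((nsp, ncell))
    tau = 0.0
    h = dt
    eval_rates_packed(flat, law, pa, pb, ia, ib, ic, net_ptr, net_idx, net_coef, surf, mask, k1)
    while tau < dt - 1e-12:
        if h > dt - tau:
            h = dt - tau
        for s in range(nsp):
            for c in range(ncell):
                v = flat[s, c] + 0.5 * h * k1[s, c]
                stage[s, c] = v if v > 0.0 else 0.0
        eval_rates_packed(stage, law, pa, pb, ia, ib, ic, net_ptr, net_idx, net_coef, surf, mask, k2)
        for s in range(nsp):
            for c in range(ncell):
                v = flat[s, c] + 0.75 * h * k2[s, c]
                stage[s, c] = v if v > 0.0 else 0.0
        eval_rates_packed(stage, law, pa, pb, ia, ib, ic, net_ptr, net_idx, net_coef, surf, mask, k3)
        for s in range(nsp):
            for c in range(ncell):
                v = flat[s, c] + h * (
                    (2.0 / 9.0) * k1[s, c] + (1.0 / 3.0) * k2[s, c] + (4.0 / 9.0) * k3[s, c]
                )
                cand[s, c] = v
                stage[s, c] = v if v > 0.0 else 0.0
        eval_rates_packed(stage, law, pa, pb, ia, ib, ic, net_ptr, net_idx, net_coef, surf, mask, k4)
        err_norm = 0.0
        for s in range(nsp):
            for c in range(ncell):
                e = h * (
                    (-5.0 / 72.0) * k1[s, c]
                    + (1.0 / 12.0) * k2[s, c]
                    + (1.0 / 9.0) * k3[s, c]
                    - (1.0 / 8.0) * k4[s, c]
                )
                y0 = abs(flat[s, c])
                y1 = abs(stage[s, c])
                sc = atol + rtol * (y0 if y0 > y1 else y1)
                en = abs(e) / sc
                if en > err_norm:
                    err_norm = en
        if err_norm <= 1.0 or h <= 1e-9:
            for s in range(nsp):
                for c in range(ncell):
                    v = cand[s, c]
                    if v < 0.0:
                        clip_out[s] -= v
                        v = 0.0
                    flat[s, c] = v
            tau += h
            tmp = k1
            k1 = k4
            k4 = tmp
        if err_norm > 0.0:
            factor = 0.9 * err_norm ** (-1.0 / 3.0)
        else:
            factor = 5.0
        if factor < 0.2:
            factor = 0.2
        elif factor > 5.0:
            factor = 5.0
        h *= factor
    return flat


@njit(cache=True)
def upwind_advect(C, u, v, inflow, dt_dx, closed_box):
    """First-order upwind update for a (n, ny, nx) stack on MAC face
    velocities u (ny, nx+1) / v (ny+1, nx).  ``inflow`` is the inlet
    Dirichlet value per species (ignored for a closed box)."""
    n, ny, nx = C.shape
    out = np.empty_like(C)
    for s in range(n):
        for j in range(ny):
            for i in range(nx):
                # east face i+1, west face i
                uw = u[j, i]
                ue = u[j, i + 1]
                if i == 0:
                    cw = inflow[s] if not closed_box else 0.0
                    fw = (uw * cw if uw > 0 else uw * C[s, j, 0]) if not closed_box else 0.0
                else:
                    fw = uw * C[s, j, i - 1] if uw > 0 else uw * C[s, j, i]
                if i == nx - 1:
                    fe = (ue * C[s, j, i] if ue > 0 else ue * C[s, j, i]) if not closed_box else 0.0
                else:
                    fe = ue * C[s, j, i] if ue > 0 else ue * C[s, j, i + 1]
                vs = v[j, i]
                vn = v[j + 1, i]
                fs = 0.0
                if j > 0:
                    fs = vs * C[s, j - 1, i] if vs > 0 else vs * C[s, j, i]
                fn = 0.0
                if j < ny - 1:
                    fn = vn * C[s, j, i] if vn > 0 else vn * C[s, j + 1, i]
                out[s, j, i] = C[s, j, i] - dt_dx * (fe - fw + fn - fs)
    return out


@njit(cache=True)
def diffuse_step(C, D, plasma, dt_dx2, closed_box):
    """Explicit 5-point diffusion for a (n, ny, nx) stack with per-species
    diffusivity D: reflective walls, zero-gradient outlet, inlet Dirichlet
    at the plasma value (ghost = 2·plasma − C)."""
    n, ny, nx = C.shape
    out = np.empty_like(C)
    for s in range(n):
        d = D[s]
        if d == 0.0:
            out[s] = C[s]
            continue
        for j in range(ny):
            for i in range(nx):
                cc = C[s, j, i]
                cw = C[s, j, i - 1] if i > 0 else (
                    cc if closed_box else 2.0 * plasma[s] - cc
                )
                ce = C[s, j, i + 1] if i < nx - 1 else cc
                cs = C[s, j - 1, i] if j > 0 else cc
                cn = C[s, j + 1, i] if j < ny - 1 else cc
                out[s, j, i] = cc + dt_dx2 * d * (cw + ce + cs + cn - 4.0 * cc)
    return out
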