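"""Numba-compiled inner loops for cell and tissue integration.

All kernels consume a packed parameter vector ``p`` produced by
``ModelParameters.pack()``:

    p[0:8]  tau_h+, tau_h-, tau_f+, tau_f-, tau_r+, tau_r-, tau_s+, tau_s-
    p[8:12] g_fi, V_fi, g_so, g_si
    p[12:16] beta_1, beta_2, V_1, V_2
    p[16:21] g_to, V_c, V_s (effective s-gate threshold), V_r, V_to

The Heaviside convention is right-continuous, Theta(0) = 1, implemented
as ``>=`` comparisons throughout.

Tissue fields are always 3D arrays (singleton axes for 1D/2D).  The
diffusion operator is in conservative flux form: the divergence at a
node is the signed sum of face fluxes divided by dx, and a face flux is
nonzero only between two in-tissue nodes, which enforces zero-flux
boundaries and makes the total voltage exactly conserved under pure
diffusion.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "integrate_cell",
    "div_scalar",
    "div_aniso",
    "react_step",
    "step_window_scalar",
    "step_window_aniso",
]


@njit(cache=True, fastmath=True)
def _cell_derivs(V, h, f, r, s, p):
    """Right-hand side of the space-clamped model (no stimulus)."""
    Vc = p[17]
    above_c = V >= Vc
    # currents
    m_inf = (V - Vc) if above_c else 0.0
    J_fi = -p[8] * h * m_inf * (p[9] - V)
    if above_c:
        d_inf = 0.5 * (1.0 + math.tanh(p[12] * (V - p[14])))
        fp_inf = 0.5 * (1.0 - math.tanh(p[13] * (V - p[15])))
        J_si = -p[11] * d_inf * f * fp_inf
        k_inf = 1.0
    else:
        J_si = 0.0
        k_inf = V / Vc
    J_so = p[10] * k_inf
    J_to = p[16] * r * s * (V - p[20])
    dV = -(J_fi + J_si + J_so + J_to)
    # gates
    if above_c:
        dh = (0.0 - h) / p[1]
        df = (0.0 - f) / p[3]
    else:
        dh = (1.0 - h) / p[0]
        df = (1.0 - f) / p[2]
    if V >= p[19]:  # V_r
        dr = (1.0 - r) / p[4]
    else:
        dr = (0.0 - r) / p[5]
    if V >= p[18]:  # effective s threshold
        ds = (0.0 - s) / p[7]
    else:
        ds = (1.0 - s) / p[6]
    return dV, dh, df, dr, ds


@njit(cache=True, fastmath=True)
def integrate_cell(y0, p, dt, n_steps, stim, rec_stride, record_gates):
    """Forward-Euler integration of one cell with a per-step stimulus.

    Records the state every ``rec_stride`` steps (including step 0 and,
    when n_steps is a multiple of rec_stride, the final step).  Returns
    an array of shape (5 or 1, n_records): row 0 is V, rows 1-4 are
    h, f, r, s when ``record_gates``.
    """
    V, h, f, r, s = y0[0], y0[1], y0[2], y0[3], y0[4]
    n_rec = n_steps // rec_stride + 1
    n_rows = 5 if record_gates else 1
    out = np.empty((n_rows, n_rec))
    k = 0
    for i in range(n_steps + 1):
        if i % rec_stride == 0:
            out[0, k] = V
            if record_gates:
                out[1, k] = h
                out[2, k] = f
                out[3, k] = r
                out[4, k] = s
            k += 1
        if i < n_steps:
            dV, dh, df, dr, ds = _cell_derivs(V, h, f, r, s, p)
            V += dt * (dV + stim[i])
            h += dt * dh
            f += dt * df
            r += dt * dr
            s += dt * ds
    return out


@njit(cache=True, fastmath=True)
def div_scalar(V, mask, D, dx, out):
    """out <- div(D grad V), scalar uniform D, flux-form, no-flux walls."""
    nx, ny, nz = V.shape
    c = D / (dx * dx)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    out[i, j, k] = 0.0
                    continue
                v = V[i, j, k]
                acc = 0.0
                if i > 0 and mask[i - 1, j, k]:
                    acc += V[i - 1, j, k] - v
                if i < nx - 1 and mask[i + 1, j, k]:
                    acc += V[i + 1, j, k] - v
                if j > 0 and mask[i, j - 1, k]:
                    acc += V[i, j - 1, k] - v
                if j < ny - 1 and mask[i, j + 1, k]:
                    acc += V[i, j + 1, k] - v
                if k > 0 and mask[i, j, k - 1]:
                    acc += V[i, j, k - 1] - v
                if k < nz - 1 and mask[i, j, k + 1]:
                    acc += V[i, j, k + 1] - v
                out[i, j, k] = c * acc


@njit(cache=True, fastmath=True)
def _face_grad_t(V, mask, i, j, k, i2, j2, k2, axis):
    """Tangential derivative along ``axis`` averaged over a face.

    The face joins nodes (i,j,k) and (i2,j2,k2).  Central differences
    at both nodes are averaged; one-sided differences are used next to
    the mask boundary and missing neighbors contribute zero.
    """
    g = 0.0
    w = 0.0
    for (a, b, c) in ((i, j, k), (i2, j2, k2)):
        if axis == 0:
            n = V.shape[0]
            lo, hi = a - 1, a + 1
            ok_lo = lo >= 0 and mask[lo, b, c]
            ok_hi = hi < n and mask[hi, b, c]
            vlo = V[lo, b, c] if ok_lo else 0.0
            vhi = V[hi, b, c] if ok_hi else 0.0
        elif axis == 1:
            n = V.shape[1]
            lo, hi = b - 1, b + 1
            ok_lo = lo >= 0 and mask[a, lo, c]
            ok_hi = hi < n and mask[a, hi, c]
            vlo = V[a, lo, c] if ok_lo else 0.0
            vhi = V[a, hi, c] if ok_hi else 0.0
        else:
            n = V.shape[2]
            lo, hi = c - 1, c + 1
            ok_lo = lo >= 0 and mask[a, b, lo]
            ok_hi = hi < n and mask[a, b, hi]
            vlo = V[a, b, lo] if ok_lo else 0.0
            vhi = V[a, b, hi] if ok_hi else 0.0
        vc = V[a, b, c]
        if ok_lo and ok_hi:
            g += 0.5 * (vhi - vlo)
            w += 1.0
        elif ok_hi:
            g += vhi - vc
            w += 1.0
        elif ok_lo:
            g += vc - vlo
            w += 1.0
    if w > 0.0:
        return g / w
    return 0.0


@njit(cache=True, fastmath=True)
def div_aniso(V, mask, T, dx, out):
    """out <- div(D grad V) for a per-node symmetric tensor field.

    ``T`` has shape (nx, ny, nz, 6) storing (Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz) in cm^2/ms.  Face tensors are arithmetic means of the two
    adjacent node tensors; cross-derivative terms use face-averaged
    tangential gradients.  Written as accumulated face fluxes so the
    scheme is exactly conservative on the masked domain.
    """
    nx, ny, nz = V.shape
    out[:, :, :] = 0.0
    inv = 1.0 / dx
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                v = V[i, j, k]
                # +x face
                if i < nx - 1 and mask[i + 1, j, k]:
                    dxx = 0.5 * (T[i, j, k, 0] + T[i + 1, j, k, 0])
                    dxy = 0.5 * (T[i, j, k, 3] + T[i + 1, j, k, 3])
                    dxz = 0.5 * (T[i, j, k, 4] + T[i + 1, j, k, 4])
                    flux = dxx * (V[i + 1, j, k] - v)
                    if dxy != 0.0:
                        flux += dxy * _face_grad_t(V, mask, i, j, k, i + 1, j, k, 1)
                    if dxz != 0.0:
                        flux += dxz * _face_grad_t(V, mask, i, j, k, i + 1, j, k, 2)
                    flux *= inv
                    out[i, j, k] += flux
                    out[i + 1, j, k] -= flux
                # +y face
                if j < ny - 1 and mask[i, j + 1, k]:
                    dyy = 0.5 * (T[i, j, k, 1] + T[i, j + 1, k, 1])
                    dxy = 0.5 * (T[i, j, k, 3] + T[i, j + 1, k, 3])
                    dyz = 0.5 * (T[i, j, k, 5] + T[i, j + 1, k, 5])
                    flux = dyy * (V[i, j + 1, k] - v)
                    if dxy != 0.0:
                        flux += dxy * _face_grad_t(V, mask, i, j, k, i, j + 1, k, 0)
                    if dyz != 0.0:
                        flux += dyz * _face_grad_t(V, mask, i, j, k, i, j + 1, k, 2)
                    flux *= inv
                    out[i, j, k] += flux
                    out[i, j + 1, k] -= flux
                # +z face
                if k < nz - 1 and mask[i, j, k + 1]:
                    dzz = 0.5 * (T[i, j, k, 2] + T[i, j, k + 1, 2])
                    dxz = 0.5 * (T[i, j, k, 4] + T[i, j, k + 1, 4])
                    dyz = 0.5 * (T[i, j, k, 5] + T[i, j, k + 1, 5])
                    flux = dzz * (V[i, j, k + 1] - v)
                    if dxz != 0.0:
                        flux += dxz * _face_grad_t(V, mask, i, j, k, i, j, k + 1, 0)
                    if dyz != 0.0:
                        flux += dyz * _face_grad_t(V, mask, i, j, k, i, j, k + 1, 1)
                    flux *= inv
                    out[i, j, k] += flux
                    out[i, j, k + 1] -= flux
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                out[i, j, k] *= inv


@njit(cache=True, fastmath=True)
def react_step(V, h, f, r, s, mask, div, jstim, p, dt):
    """In-place forward-Euler update of all five fields over one dt."""
    nx, ny, nz = V.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                dV, dh, df, dr, ds = _cell_derivs(
                    V[i, j, k], h[i, j, k], f[i, j, k], r[i, j, k],
                    s[i, j, k], p)
                V[i, j, k] += dt * (dV + div[i, j, k] + jstim[i, j, k])
                h[i, j, k] += dt * dh
                f[i, j, k] += dt * df
                r[i, j, k] += dt * dr
                s[i, j, k] += dt * ds


#: Sigmoid lookup-table domain shared by make_sigmoid_tables and the
#: fused kernel: voltages [TAB_V0, TAB_V1], TAB_N samples.
TAB_V0 = 0.0
TAB_V1 = 2.6
TAB_N = 4096


def make_sigmoid_tables(p):
    """Tabulate d_inf (without the threshold step) and f'_inf.

    The fused tissue kernel replaces the two tanh evaluations per node
    per step by linear interpolation in these tables; with 4096 points
    over [0, 2.6] the absolute error is below 1e-5, far under the
    discretization error of the explicit scheme.
    """
    v = np.linspace(TAB_V0, TAB_V1, TAB_N)
    dtab = 0.5 * (1.0 + np.tanh(p[12] * (v - p[14])))
    fptab = 0.5 * (1.0 - np.tanh(p[13] * (v - p[15])))
    inv_dv = (TAB_N - 1) / (TAB_V1 - TAB_V0)
    return dtab, fptab, inv_dv


@njit(cache=True, fastmath=True)
def step_window_scalar(V, h, f, r, s, mask, D, dx, p, dt, n_sub, jstim, Vbuf,
                       dtab, fptab, inv_dv):
    """Fused diffusion+reaction window for scalar uniform D.

    Single pass per substep: the new voltage is written to a swap
    buffer (neighbor reads always see the old field) while gates update
    in place.  After an odd number of substeps the result is copied
    back so the caller's arrays hold the final state.
    """
    nx, ny, nz = V.shape
    c = D / (dx * dx)
    thp = p[0]; thm = p[1]; tfp = p[2]; tfm = p[3]
    trp = p[4]; trm = p[5]; tsp = p[6]; tsm = p[7]
    gfi = p[8]; Vfi = p[9]; gso = p[10]; gsi = p[11]
    b1 = p[12]; b2 = p[13]; V1 = p[14]; V2 = p[15]
    gto = p[16]; Vc = p[17]; Vs = p[18]; Vr = p[19]; Vto = p[20]
    i_thp = 1.0 / thp; i_thm = 1.0 / thm
    i_tfp = 1.0 / tfp; i_tfm = 1.0 / tfm
    i_trp = 1.0 / trp; i_trm = 1.0 / trm
    i_tsp = 1.0 / tsp; i_tsm = 1.0 / tsm
    i_Vc = 1.0 / Vc
    A = V
    B = Vbuf
    B[:, :, :] = A  # keep non-tissue nodes consistent in both buffers
    for it in range(n_sub):
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if not mask[i, j, k]:
                        continue
                    v = A[i, j, k]
                    acc = 0.0
                    if i > 0 and mask[i - 1, j, k]:
                        acc += A[i - 1, j, k] - v
                    if i < nx - 1 and mask[i + 1, j, k]:
                        acc += A[i + 1, j, k] - v
                    if j > 0 and mask[i, j - 1, k]:
                        acc += A[i, j - 1, k] - v
                    if j < ny - 1 and mask[i, j + 1, k]:
                        acc += A[i, j + 1, k] - v
                    if k > 0 and mask[i, j, k - 1]:
                        acc += A[i, j, k - 1] - v
                    if k < nz - 1 and mask[i, j, k + 1]:
                        acc += A[i, j, k + 1] - v
                    hh = h[i, j, k]
                    ff = f[i, j, k]
                    rr = r[i, j, k]
                    ss = s[i, j, k]
                    if v >= Vc:
                        J_fi = -gfi * hh * (v - Vc) * (Vfi - v)
                        u = (v - TAB_V0) * inv_dv
                        iu = int(u)
                        if iu < 0:
                            iu = 0
                            wu = 0.0
                        elif iu > TAB_N - 2:
                            iu = TAB_N - 2
                            wu = 1.0
                        else:
                            wu = u - iu
                        d_inf = dtab[iu] + (dtab[iu + 1] - dtab[iu]) * wu
                        fp_inf = fptab[iu] + (fptab[iu + 1] - fptab[iu]) * wu
                        J_si = -gsi * d_inf * ff * fp_inf
                        J_so = gso
                        h[i, j, k] = hh - dt * hh * i_thm
                        f[i, j, k] = ff - dt * ff * i_tfm
                    else:
                        J_fi = 0.0
                        J_si = 0.0
                        J_so = gso * v * i_Vc
                        h[i, j, k] = hh + dt * (1.0 - hh) * i_thp
                        f[i, j, k] = ff + dt * (1.0 - ff) * i_tfp
                    J_to = gto * rr * ss * (v - Vto)
                    if v >= Vr:
                        r[i, j, k] = rr + dt * (1.0 - rr) * i_trp
                    else:
                        r[i, j, k] = rr - dt * rr * i_trm
                    if v >= Vs:
                        s[i, j, k] = ss - dt * ss * i_tsm
                    else:
                        s[i, j, k] = ss + dt * (1.0 - ss) * i_tsp
                    B[i, j, k] = v + dt * (c * acc
                                           - (J_fi + J_si + J_so + J_to)
                                           + jstim[i, j, k])
        A, B = B, A
    if n_sub % 2 == 1:
        # A (latest) is the caller's Vbuf; copy back into the caller's V
        B[:, :, :] = A


@njit(cache=True, fastmath=True)
def step_window_aniso(V, h, f, r, s, mask, T, dx, p, dt, n_sub, jstim, div):
    for _ in range(n_sub):
        div_aniso(V, mask, T, dx, div)
        react_step(V, h, f, r, s, mask, div, jstim, p, dt)
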