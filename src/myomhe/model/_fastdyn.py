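"""Numba-compiled batched state derivative.

The multiple-shooting transcription evaluates the musculoskeletal ODE on
batches of tens of thousands of (state, control) pairs (all shooting
intervals x all complex-step directions), which dominates the runtime of
every solve.  This module provides a scalar-per-element compiled kernel
equivalent to :func:`myomhe.model.dynamics.forward_dynamics`; the numpy
implementation remains the reference and the test suite asserts the two
paths agree to machine precision.

Everything runs on complex128 so the same kernel serves both nominal
evaluations and complex-step differentiation.
"""

from __future__ import annotations

import cmath

import numpy as np

try:
    from numba import njit
    NUMBA_AVAILABLE = True
except Exception:  # pragma: no cover - numba is a hard dep of the env
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

_FV_K = 3.0
_FV_SCALE = 1.0 / float(np.arcsinh(3.0))
_FP_K = 4.0
_FP_DEN = float(np.expm1(_FP_K * 0.7))


@njit(cache=True)
def _xdot_batch(x, u, out, parent, jo_local, axis_local, anc_u8,
                body_frame, body_mass, body_com, body_inertia, gravity,
                point_frame, point_local, edge_a, edge_b, edge_muscle,
                f_iso, l_opt, l_ts, v_max, tau_act, tau_deact,
                exc_driven):
    B = x.shape[0]
    nq = parent.shape[0]
    nmus = f_iso.shape[0]
    npts = point_frame.shape[0]
    nedg = edge_a.shape[0]
    nbod = body_frame.shape[0]
    F = nq + 1

    for b in range(B):
        # ---------------- forward kinematics along the chain
        R = np.zeros((F, 3, 3), dtype=np.complex128)
        o = np.zeros((F, 3), dtype=np.complex128)
        aw = np.zeros((nq, 3), dtype=np.complex128)
        jo = np.zeros((nq, 3), dtype=np.complex128)
        R[0, 0, 0] = 1.0
        R[0, 1, 1] = 1.0
        R[0, 2, 2] = 1.0
        for j in range(nq):
            p = parent[j]
            for i in range(3):
                cen = o[p, i]
                axw = 0.0 + 0.0j
                for k in range(3):
                    cen += R[p, i, k] * jo_local[j, k]
                    axw += R[p, i, k] * axis_local[j, k]
                jo[j, i] = cen
                aw[j, i] = axw
            th = x[b, j]
            c = cmath.cos(th)
            s = cmath.sin(th)
            ax = axis_local[j]
            # local Rodrigues rotation about the (unit) joint axis
            rl = np.empty((3, 3), dtype=np.complex128)
            for i in range(3):
                for k in range(3):
                    rl[i, k] = (1.0 - c) * ax[i] * ax[k]
                rl[i, i] = rl[i, i] + c
            rl[0, 1] -= s * ax[2]
            rl[0, 2] += s * ax[1]
            rl[1, 0] += s * ax[2]
            rl[1, 2] -= s * ax[0]
            rl[2, 0] -= s * ax[1]
            rl[2, 1] += s * ax[0]
            for i in range(3):
                o[j + 1, i] = jo[j, i]
                for k in range(3):
                    acc = 0.0 + 0.0j
                    for m in range(3):
                        acc += R[p, i, m] * rl[m, k]
                    R[j + 1, i, k] = acc

        # ---------------- muscle polyline geometry
        pw = np.empty((npts, 3), dtype=np.complex128)
        for pt in range(npts):
            f = point_frame[pt]
            for i in range(3):
                acc = o[f, i]
                for k in range(3):
                    acc += R[f, i, k] * point_local[pt, k]
                pw[pt, i] = acc
        l_mt = np.zeros(nmus, dtype=np.complex128)
        dl_dq = np.zeros((nmus, nq), dtype=np.complex128)
        for e in range(nedg):
            ia = edge_a[e]
            ib = edge_b[e]
            mu = edge_muscle[e]
            d0 = pw[ib, 0] - pw[ia, 0]
            d1 = pw[ib, 1] - pw[ia, 1]
            d2 = pw[ib, 2] - pw[ia, 2]
            L = cmath.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
            l_mt[mu] += L
            u0 = d0 / L
            u1 = d1 / L
            u2 = d2 / L
            fa = point_frame[ia]
            fb = point_frame[ib]
            for j in range(nq):
                g = 0.0 + 0.0j
                if anc_u8[j, fb] != 0:
                    # unit . (a_j x (p_b - o_j))
                    r0 = pw[ib, 0] - jo[j, 0]
                    r1 = pw[ib, 1] - jo[j, 1]
                    r2 = pw[ib, 2] - jo[j, 2]
                    g += (u0 * (aw[j, 1] * r2 - aw[j, 2] * r1)
                          + u1 * (aw[j, 2] * r0 - aw[j, 0] * r2)
                          + u2 * (aw[j, 0] * r1 - aw[j, 1] * r0))
                if anc_u8[j, fa] != 0:
                    r0 = pw[ia, 0] - jo[j, 0]
                    r1 = pw[ia, 1] - jo[j, 1]
                    r2 = pw[ia, 2] - jo[j, 2]
                    g -= (u0 * (aw[j, 1] * r2 - aw[j, 2] * r1)
                          + u1 * (aw[j, 2] * r0 - aw[j, 0] * r2)
                          + u2 * (aw[j, 0] * r1 - aw[j, 1] * r0))
                dl_dq[mu, j] += g

        # ---------------- Hill forces and joint torques
        tau = np.zeros(nq, dtype=np.complex128)
        for m in range(nmus):
            vm = 0.0 + 0.0j
            for j in range(nq):
                vm += dl_dq[m, j] * x[b, nq + j]
            ln = (l_mt[m] - l_ts[m]) / l_opt[m]
            vn = vm / (l_opt[m] * v_max[m])
            if exc_driven:
                act = x[b, 2 * nq + m]
            else:
                act = u[b, m]
            fl = cmath.exp(-((ln - 1.0) ** 2) / 0.45)
            z = _FV_K * vn
            fv = 1.0 + _FV_SCALE * cmath.log(z + cmath.sqrt(z * z + 1.0))
            if ln.real > 1.0:
                fp = (cmath.exp(_FP_K * (ln - 1.0)) - 1.0) / _FP_DEN
            else:
                fp = 0.0 + 0.0j
            fm = f_iso[m] * (act * fl * fv + fp)
            for j in range(nq):
                tau[j] -= dl_dq[m, j] * fm

        # ---------------- Newton-Euler sweep (qdd = 0) for nle
        omg = np.zeros((F, 3), dtype=np.complex128)
        alp = np.zeros((F, 3), dtype=np.complex128)
        aor = np.zeros((F, 3), dtype=np.complex128)
        for j in range(nq):
            p = parent[j]
            r0 = jo[j, 0] - o[p, 0]
            r1 = jo[j, 1] - o[p, 1]
            r2 = jo[j, 2] - o[p, 2]
            w0, w1, w2 = omg[p, 0], omg[p, 1], omg[p, 2]
            # a_c = a_op + alp_p x r + w x (w x r)
            c0 = alp[p, 1] * r2 - alp[p, 2] * r1
            c1 = alp[p, 2] * r0 - alp[p, 0] * r2
            c2 = alp[p, 0] * r1 - alp[p, 1] * r0
            wr0 = w1 * r2 - w2 * r1
            wr1 = w2 * r0 - w0 * r2
            wr2 = w0 * r1 - w1 * r0
            aor[j + 1, 0] = aor[p, 0] + c0 + (w1 * wr2 - w2 * wr1)
            aor[j + 1, 1] = aor[p, 1] + c1 + (w2 * wr0 - w0 * wr2)
            aor[j + 1, 2] = aor[p, 2] + c2 + (w0 * wr1 - w1 * wr0)
            qdj = x[b, nq + j]
            omg[j + 1, 0] = w0 + qdj * aw[j, 0]
            omg[j + 1, 1] = w1 + qdj * aw[j, 1]
            omg[j + 1, 2] = w2 + qdj * aw[j, 2]
            alp[j + 1, 0] = alp[p, 0] + (w1 * qdj * aw[j, 2]
                                         - w2 * qdj * aw[j, 1])
            alp[j + 1, 1] = alp[p, 1] + (w2 * qdj * aw[j, 0]
                                         - w0 * qdj * aw[j, 2])
            alp[j + 1, 2] = alp[p, 2] + (w0 * qdj * aw[j, 1]
                                         - w1 * qdj * aw[j, 0])

        nle = np.zeros(nq, dtype=np.complex128)
        M = np.zeros((nq, nq), dtype=np.complex128)
        Jv = np.empty((3, nq), dtype=np.complex128)
        Jw = np.empty((3, nq), dtype=np.complex128)
        Iw = np.empty((3, 3), dtype=np.complex128)
        for bd in range(nbod):
            f = body_frame[bd]
            # CoM world position
            cw0 = o[f, 0]
            cw1 = o[f, 1]
            cw2 = o[f, 2]
            for k in range(3):
                cw0 += R[f, 0, k] * body_com[bd, k]
                cw1 += R[f, 1, k] * body_com[bd, k]
                cw2 += R[f, 2, k] * body_com[bd, k]
            # world inertia Iw = R I R^T
            for i in range(3):
                for k in range(3):
                    acc = 0.0 + 0.0j
                    for m in range(3):
                        acc += R[f, i, m] * body_inertia[bd, m, m] * R[f, k, m]
                    Iw[i, k] = acc
            # Jacobians
            for j in range(nq):
                if anc_u8[j, f] != 0:
                    r0 = cw0 - jo[j, 0]
                    r1 = cw1 - jo[j, 1]
                    r2 = cw2 - jo[j, 2]
                    Jv[0, j] = aw[j, 1] * r2 - aw[j, 2] * r1
                    Jv[1, j] = aw[j, 2] * r0 - aw[j, 0] * r2
                    Jv[2, j] = aw[j, 0] * r1 - aw[j, 1] * r0
                    Jw[0, j] = aw[j, 0]
                    Jw[1, j] = aw[j, 1]
                    Jw[2, j] = aw[j, 2]
                else:
                    for i in range(3):
                        Jv[i, j] = 0.0
                        Jw[i, j] = 0.0
            # mass matrix contribution
            for j in range(nq):
                for k in range(j, nq):
                    acc = 0.0 + 0.0j
                    for i in range(3):
                        acc += body_mass[bd] * Jv[i, j] * Jv[i, k]
                        iwj = (Iw[i, 0] * Jw[0, k] + Iw[i, 1] * Jw[1, k]
                               + Iw[i, 2] * Jw[2, k])
                        acc += Jw[i, j] * iwj
                    M[j, k] += acc
            # body wrench with qdd = 0
            w0, w1, w2 = omg[f, 0], omg[f, 1], omg[f, 2]
            al0, al1, al2 = alp[f, 0], alp[f, 1], alp[f, 2]
            rc0 = cw0 - o[f, 0]
            rc1 = cw1 - o[f, 1]
            rc2 = cw2 - o[f, 2]
            wr0 = w1 * rc2 - w2 * rc1
            wr1 = w2 * rc0 - w0 * rc2
            wr2 = w0 * rc1 - w1 * rc0
            ac0 = aor[f, 0] + (al1 * rc2 - al2 * rc1) + (w1 * wr2 - w2 * wr1)
            ac1 = aor[f, 1] + (al2 * rc0 - al0 * rc2) + (w2 * wr0 - w0 * wr2)
            ac2 = aor[f, 2] + (al0 * rc1 - al1 * rc0) + (w0 * wr1 - w1 * wr0)
            fb0 = body_mass[bd] * (ac0 - gravity[0])
            fb1 = body_mass[bd] * (ac1 - gravity[1])
            fb2 = body_mass[bd] * (ac2 - gravity[2])
            iw_w0 = Iw[0, 0] * w0 + Iw[0, 1] * w1 + Iw[0, 2] * w2
            iw_w1 = Iw[1, 0] * w0 + Iw[1, 1] * w1 + Iw[1, 2] * w2
            iw_w2 = Iw[2, 0] * w0 + Iw[2, 1] * w1 + Iw[2, 2] * w2
            nb0 = (Iw[0, 0] * al0 + Iw[0, 1] * al1 + Iw[0, 2] * al2
                   + w1 * iw_w2 - w2 * iw_w1)
            nb1 = (Iw[1, 0] * al0 + Iw[1, 1] * al1 + Iw[1, 2] * al2
                   + w2 * iw_w0 - w0 * iw_w2)
            nb2 = (Iw[2, 0] * al0 + Iw[2, 1] * al1 + Iw[2, 2] * al2
                   + w0 * iw_w1 - w1 * iw_w0)
            for j in range(nq):
                if anc_u8[j, f] != 0:
                    r0 = cw0 - jo[j, 0]
                    r1 = cw1 - jo[j, 1]
                    r2 = cw2 - jo[j, 2]
                    m0 = nb0 + (r1 * fb2 - r2 * fb1)
                    m1 = nb1 + (r2 * fb0 - r0 * fb2)
                    m2 = nb2 + (r0 * fb1 - r1 * fb0)
                    nle[j] += aw[j, 0] * m0 + aw[j, 1] * m1 + aw[j, 2] * m2
        for j in range(nq):
            for k in range(j):
                M[j, k] = M[k, j]

        # ---------------- solve M qdd = tau - nle (gaussian elimination)
        rhs = np.empty(nq, dtype=np.complex128)
        for j in range(nq):
            rhs[j] = tau[j] - nle[j]
        for j in range(nq):
            piv = M[j, j]
            for k in range(j + 1, nq):
                fac = M[k, j] / piv
                for m in range(j, nq):
                    M[k, m] -= fac * M[j, m]
                rhs[k] -= fac * rhs[j]
        for j in range(nq - 1, -1, -1):
            acc = rhs[j]
            for k in range(j + 1, nq):
                acc -= M[j, k] * rhs[k]
            rhs[j] = acc / M[j, j]

        # ---------------- assemble xdot
        for j in range(nq):
            out[b, j] = x[b, nq + j]
            out[b, nq + j] = rhs[j]
        if exc_driven:
            for m in range(nmus):
                a = x[b, 2 * nq + m]
                e = u[b, m]
                arg = (e - a) / 0.02
                ar = arg.real
                if ar > 40.0:
                    arg = 40.0 + (arg - ar)
                elif ar < -40.0:
                    arg = -40.0 + (arg - ar)
                sg = 1.0 / (1.0 + cmath.exp(-arg))
                taua = tau_deact[m] + (tau_act[m] - tau_deact[m]) * sg
                out[b, 2 * nq + m] = (e - a) / taua


def fast_pack(cm):
    """Constant arrays of a CompiledModel in kernel-ready layout."""
    return (cm.parent.astype(np.int64), cm.joint_origin_local,
            cm.axis_local, cm.ancestor.astype(np.uint8),
            cm.body_frame.astype(np.int64), cm.body_mass, cm.body_com,
            cm.body_inertia, cm.gravity,
            cm.point_frame.astype(np.int64), cm.point_local,
            cm.edge_a.astype(np.int64), cm.edge_b.astype(np.int64),
            cm.edge_muscle.astype(np.int64), cm.f_iso_max, cm.l_opt,
            cm.l_ts, cm.v_max, cm.tau_act, cm.tau_deact)


def forward_dynamics_fast(cm, x, u, excitation_driven=True):
    """Batched state derivative via the compiled kernel.

    Accepts (B, nx) / (B, nu) arrays of any real or complex dtype and
    returns complex128 output of shape (B, nx).
    """
    pack = getattr(cm, "_fast_pack", None)
    if pack is None:
        pack = fast_pack(cm)
        cm._fast_pack = pack
    x = np.ascontiguousarray(x, dtype=np.complex128)
    u = np.ascontiguousarray(u, dtype=np.complex128)
    out = np.empty_like(x)
    _xdot_batch(x, u, out, *pack, excitation_driven)
    return out
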