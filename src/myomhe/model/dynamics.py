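"""Rigid-body and muscle dynamics of the arm chain.

The equations of motion are M(q) qdd + nle(q, qd) = tau with tau the
joint torques produced by the muscle forces through the moment arms.
The mass matrix is assembled from body Jacobians (kinetic-energy route),
M = sum_b m_b Jv_b^T Jv_b + Jw_b^T I_b^w Jw_b, while the nonlinear
effects (Coriolis, centrifugal, gravity) come from a world-frame
Newton-Euler sweep with zero joint acceleration.  Everything is batched
and complex-step differentiable; the full state derivative computes the
frame kinematics once and shares it across the muscle-geometry, mass
matrix and bias-force passes (this function dominates the optimal
control runtime).
"""

from __future__ import annotations

import numpy as np

from .kinematics import CompiledModel, Frames, cross3
from .muscle import activation_rate, hill_force, musculotendon_geometry


class IntegrationBlowupError(RuntimeError):
    """Non-finite state encountered inside a shooting interval."""


def _body_jacobians(cm: CompiledModel, fr: Frames):
    """CoM linear and angular Jacobians for every rigid body."""
    Rb = fr.R[..., cm.body_frame, :, :]
    com_w = fr.origin[..., cm.body_frame, :] + np.einsum(
        "...bij,bj->...bi", Rb, cm.body_com)
    Jv = cm.point_jacobians(fr, cm.body_frame, com_w)       # (..., B, 3, nq)
    mask = cm.ancestor[:, cm.body_frame].T                  # (B, nq)
    Jw_cols = fr.axis_w[..., None, :, :] * mask[..., :, :, None]
    Jw = np.swapaxes(Jw_cols, -1, -2)                       # (..., B, 3, nq)
    return com_w, Rb, Jv, Jw


def mass_matrix(cm: CompiledModel, q: np.ndarray,
                fr: Frames | None = None) -> np.ndarray:
    """Joint-space mass matrix M(q), shape (..., nq, nq)."""
    if fr is None:
        fr = cm.frames(q)
    _, Rb, Jv, Jw = _body_jacobians(cm, fr)
    I_w = Rb @ cm.body_inertia @ np.swapaxes(Rb, -1, -2)
    M = np.einsum("b,...bik,...bil->...kl", cm.body_mass, Jv, Jv)
    M = M + np.einsum("...bik,...bij,...bjl->...kl", Jw, I_w, Jw)
    return M


def nle_forces(cm: CompiledModel, q: np.ndarray, qd: np.ndarray,
               fr: Frames | None = None) -> np.ndarray:
    """Coriolis/centrifugal + gravity generalized forces nle(q, qd)."""
    return inverse_dynamics(cm, q, qd, np.zeros_like(q), fr=fr)


def inverse_dynamics(cm: CompiledModel, q: np.ndarray, qd: np.ndarray,
                     qdd: np.ndarray, gravity: np.ndarray | None = None,
                     fr: Frames | None = None) -> np.ndarray:
    """Generalized forces realizing (q, qd, qdd).

    World-frame Newton-Euler sweep; gravity enters via d'Alembert (body
    force m (a_com - g)).  Shape (..., nq).
    """
    g = cm.gravity if gravity is None else np.asarray(gravity, float)
    if fr is None:
        fr = cm.frames(q)
    batch = q.shape[:-1]
    dtype = q.dtype if np.iscomplexobj(q) else float
    omega = np.zeros(batch + (cm.nq + 1, 3), dtype=dtype)
    alpha = np.zeros(batch + (cm.nq + 1, 3), dtype=dtype)
    a_origin = np.zeros(batch + (cm.nq + 1, 3), dtype=dtype)
    for j in range(cm.nq):
        p = cm.parent[j]
        r = fr.joint_origin[..., j, :] - fr.origin[..., p, :]
        wp, ap = omega[..., p, :], alpha[..., p, :]
        a_c = (a_origin[..., p, :] + cross3(ap, r)
               + cross3(wp, cross3(wp, r)))
        a_w = fr.axis_w[..., j, :]
        omega[..., j + 1, :] = wp + qd[..., j, None] * a_w
        alpha[..., j + 1, :] = (ap + qdd[..., j, None] * a_w
                                + cross3(wp, qd[..., j, None] * a_w))
        a_origin[..., j + 1, :] = a_c

    com_w, Rb, _, _ = _body_jacobians(cm, fr)
    wb = omega[..., cm.body_frame, :]
    ab = alpha[..., cm.body_frame, :]
    rc = com_w - fr.origin[..., cm.body_frame, :]
    a_com = (a_origin[..., cm.body_frame, :] + cross3(ab, rc)
             + cross3(wb, cross3(wb, rc)))
    f_b = cm.body_mass[:, None] * (a_com - g)                  # (..., B, 3)
    I_w = Rb @ cm.body_inertia @ np.swapaxes(Rb, -1, -2)
    n_b = (np.einsum("...bij,...bj->...bi", I_w, ab)
           + cross3(wb, np.einsum("...bij,...bj->...bi", I_w, wb)))

    # project each body wrench onto every ancestor joint axis
    rel = com_w[..., :, None, :] - fr.joint_origin[..., None, :, :]
    mom = n_b[..., :, None, :] + cross3(rel, f_b[..., :, None, :])
    proj = np.sum(fr.axis_w[..., None, :, :] * mom, axis=-1)   # (..., B, nq)
    mask = cm.ancestor[:, cm.body_frame].T                     # (B, nq)
    return np.sum(proj * mask, axis=-2)


def muscle_torques(cm: CompiledModel, q: np.ndarray, qd: np.ndarray,
                   a: np.ndarray, fr: Frames | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Joint torques from muscle forces; returns (tau, forces)."""
    l_mt, dl_dq, v_mt = musculotendon_geometry(cm, q, qd, fr=fr)
    forces = hill_force(cm, a, l_mt, v_mt)
    tau = -np.einsum("...mq,...m->...q", dl_dq, forces)
    return tau, forces


def split_state(cm: CompiledModel, x: np.ndarray, excitation_driven: bool):
    nq = cm.nq
    q = x[..., :nq]
    qd = x[..., nq:2 * nq]
    a = x[..., 2 * nq:] if excitation_driven else None
    return q, qd, a


def forward_dynamics(cm: CompiledModel, x: np.ndarray, u: np.ndarray,
                     excitation_driven: bool = True) -> np.ndarray:
    """State derivative f(x, u) of the musculoskeletal ODE.

    Excitation-driven: x = (q, qd, a), u = excitations; appends the
    activation dynamics.  Activation-driven: x = (q, qd), u = activations.
    """
    q, qd, a = split_state(cm, x, excitation_driven)
    act = a if excitation_driven else u
    fr = cm.frames(q)
    tau, _ = muscle_torques(cm, q, qd, act, fr=fr)
    M = mass_matrix(cm, q, fr=fr)
    rhs = tau - nle_forces(cm, q, qd, fr=fr)
    qdd = np.linalg.solve(M, rhs[..., None])[..., 0]
    parts = [qd, qdd]
    if excitation_driven:
        parts.append(activation_rate(cm, a, u))
    return np.concatenate(parts, axis=-1)


#: route batched interval integration through the numba kernel when it
#: is importable; the numpy path remains the reference implementation
USE_FAST_KERNEL = True


def _dynamics_fn(x: np.ndarray):
    from . import _fastdyn
    if (USE_FAST_KERNEL and _fastdyn.NUMBA_AVAILABLE
            and np.asarray(x).ndim == 2):
        return _fastdyn.forward_dynamics_fast
    return forward_dynamics


def integrate_interval(cm: CompiledModel, x0: np.ndarray, u_const: np.ndarray,
                       dt: float, n_steps: int = 1,
                       excitation_driven: bool = True,
                       check: bool = True) -> np.ndarray:
    """Explicit 4th-order Runge-Kutta over one shooting interval with
    piecewise-constant control; deterministic."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    h = dt / n_steps
    x = np.asarray(x0)
    f = _dynamics_fn(x)
    squeeze_imag = not np.iscomplexobj(x)
    for k in range(n_steps):
        k1 = f(cm, x, u_const, excitation_driven)
        k2 = f(cm, x + 0.5 * h * k1, u_const, excitation_driven)
        k3 = f(cm, x + 0.5 * h * k2, u_const, excitation_driven)
        k4 = f(cm, x + h * k3, u_const, excitation_driven)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if check and not np.all(np.isfinite(np.real(x))):
            raise IntegrationBlowupError(
                f"non-finite state in RK4 substep {k + 1}/{n_steps} (dt={dt})")
    if squeeze_imag and np.iscomplexobj(x):
        x = x.real.copy()
    return x
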