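"""Hill-type muscle mechanics: polyline geometry, force curves, activation.

The tendon is rigid (fiber length = musculotendon length minus tendon
slack length), so muscle force is an algebraic function of the joint
state and the activation -- the muscle contributes no extra state beyond
the activation itself.  Curve shapes:

* active force-length  f_l(l) = exp(-(l - 1)^2 / 0.45)   (Gaussian),
* force-velocity       f_v(v) = 1 + asinh(k v) / asinh(k), k = 3
  (smooth sigmoid with f_v(0) = 1 and f_v(-1) = 0),
* passive force-length f_p(l) = (exp(k_p (l - 1)) - 1) / (exp(0.7 k_p) - 1)
  for l > 1 and exactly 0 below, k_p = 4 (so f_p(1.7) = 1, f_p(1.25) ~ 0.11).

All functions are vectorised over muscles and arbitrary batch dims and
are safe under complex-step differentiation (branching is done on the
real part only).
"""

from __future__ import annotations

import numpy as np

from .kinematics import CompiledModel

_FV_K = 3.0
_FV_SCALE = 1.0 / np.arcsinh(_FV_K)
_FP_K = 4.0
_FP_DEN = np.expm1(_FP_K * 0.7)


class DegenerateGeometryError(ValueError):
    """A muscle path segment has (near-)coincident endpoints."""


class NonPhysicalGeometryError(ValueError):
    """Musculotendon length does not exceed tendon slack length."""


def musculotendon_geometry(cm: CompiledModel, q: np.ndarray,
                           qdot: np.ndarray | None = None, fr=None):
    """Lengths, moment arms and (optionally) lengthening velocities.

    Returns ``(l_mt, dl_dq, v_mt)`` with shapes (..., M), (..., M, nq)
    and (..., M).  The moment-arm matrix of the field's convention is
    ``-dl_dq``.  ``v_mt`` is ``None`` when ``qdot`` is not given.
    """
    if fr is None:
        fr = cm.frames(q)
    pw = cm.points_world(fr, cm.point_frame, cm.point_local)
    jac = cm.point_jacobians(fr, cm.point_frame, pw)
    d = pw[..., cm.edge_b, :] - pw[..., cm.edge_a, :]          # (..., E, 3)
    seg_len = np.sqrt(np.sum(d * d, axis=-1))                  # (..., E)
    if np.any(np.real(seg_len) < 1e-9):
        raise DegenerateGeometryError(
            "coincident consecutive muscle path points (undefined direction)")
    unit = d / seg_len[..., None]
    djac = jac[..., cm.edge_b, :, :] - jac[..., cm.edge_a, :, :]
    seg_grad = np.einsum("...ei,...eiq->...eq", unit, djac)    # (..., E, nq)

    S = cm.muscle_edge_sum
    l_mt = np.einsum("...e,me->...m", seg_len, S)
    dl_dq = np.einsum("...eq,me->...mq", seg_grad, S)
    v_mt = None
    if qdot is not None:
        v_mt = np.einsum("...mq,...q->...m", dl_dq, qdot)
    return l_mt, dl_dq, v_mt


def moment_arms(cm: CompiledModel, q: np.ndarray) -> np.ndarray:
    """Moment-arm matrix R = -dl_mt/dq, shape (..., M, nq), meters."""
    _, dl_dq, _ = musculotendon_geometry(cm, q)
    return -dl_dq


def force_length(l_norm: np.ndarray) -> np.ndarray:
    return np.exp(-((l_norm - 1.0) ** 2) / 0.45)


def force_velocity(v_norm: np.ndarray) -> np.ndarray:
    return 1.0 + _FV_SCALE * np.arcsinh(_FV_K * v_norm)


def passive_force(l_norm: np.ndarray) -> np.ndarray:
    stretched = np.real(l_norm) > 1.0
    val = np.expm1(_FP_K * (l_norm - 1.0)) / _FP_DEN
    return np.where(stretched, val, np.zeros_like(val))


def hill_force(cm: CompiledModel, a: np.ndarray, l_mt: np.ndarray,
               v_mt: np.ndarray, check: bool = False) -> np.ndarray:
    """Tendon force (N) of every muscle, rigid-tendon Hill model.

    F = F_iso_max * (a * f_l * f_v + f_p) evaluated at the normalized
    fiber length (l_mt - l_ts)/l_opt and velocity v_mt/(l_opt * v_max).
    """
    l_f = l_mt - cm.l_ts
    if check and np.any(np.real(l_f) <= 0):
        raise NonPhysicalGeometryError(
            "musculotendon length <= tendon slack length")
    l_norm = l_f / cm.l_opt
    v_norm = v_mt / (cm.l_opt * cm.v_max)
    active = a * force_length(l_norm) * force_velocity(v_norm)
    return cm.f_iso_max * (active + passive_force(l_norm))


def activation_rate(cm: CompiledModel, a: np.ndarray,
                    e: np.ndarray) -> np.ndarray:
    """First-order activation dynamics da/dt = (e - a)/tau(a, e).

    tau blends smoothly between tau_act (e > a) and tau_deact (e < a)
    over a 0.02 excitation half-width so the ODE stays differentiable;
    the fixed point a = e is exact either way.
    """
    s = _sigmoid((e - a) / 0.02)
    tau = cm.tau_deact + (cm.tau_act - cm.tau_deact) * s
    return (e - a) / tau


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # complex-safe logistic; clip the real part only to avoid overflow
    z = np.asarray(x)
    re = np.real(z)
    return 1.0 / (1.0 + np.exp(-(np.clip(re, -40.0, 40.0) + (z - re))))
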