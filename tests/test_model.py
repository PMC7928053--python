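"""Model layer: kinematics, muscle mechanics, rigid-body dynamics.

Each numerical routine is checked against an independent oracle written
in this file (explicit rotation chains, finite differences, a textbook
Newton-Euler sweep, closed-form curve values), never against the
implementation it tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.spatial.transform import Rotation

from myomhe.model import (CompiledModel, ModelValidationError,
                          MusculoskeletalModel, activation_rate, arm_model,
                          force_length, force_velocity, forward_dynamics,
                          forward_kinematics, hill_force, integrate_interval,
                          inverse_dynamics, mass_matrix, moment_arms,
                          musculotendon_geometry, passive_force,
                          planar_fixture_model)
from myomhe.model.dynamics import muscle_torques, nle_forces

from conftest import random_configurations


# ------------------------------------------------------------ FK oracle
def _fk_oracle(model: MusculoskeletalModel, q: np.ndarray) -> np.ndarray:
    """Marker positions via an explicit scipy-Rotation chain."""
    frames = {"ground": (np.eye(3), np.zeros(3))}
    for j, joint in enumerate(model.joints):
        Rp, op = frames[joint.parent]
        centre = op + Rp @ np.asarray(joint.origin)
        axis = np.asarray(joint.axis, float)
        axis = axis / np.linalg.norm(axis)
        Rj = Rp @ Rotation.from_rotvec(axis * q[j]).as_matrix()
        frames[joint.name] = (Rj, centre)
    seg_frame = {s.name: s.frame for s in model.segments}
    out = []
    for mk in model.markers:
        R, o = frames[seg_frame[mk.segment]]
        out.append(o + R @ np.asarray(mk.position))
    return np.array(out)


@pytest.mark.parametrize("builder", [planar_fixture_model, arm_model])
def test_forward_kinematics_matches_rotation_chain(builder):
    model = builder()
    cm = CompiledModel(model)
    rng = np.random.default_rng(7)
    for _ in range(10):
        q = cm.q_lower + (cm.q_upper - cm.q_lower) * rng.random(cm.nq)
        markers, hom = forward_kinematics(cm, q)
        expected = _fk_oracle(model, q)
        assert markers.shape == (model.n_markers, 3)
        np.testing.assert_allclose(markers, expected, atol=1e-10)
        assert hom.shape == (cm.nq + 1, 4, 4)


def test_neutral_pose_markers_follow_frame_chain(fixture_cm):
    """At q = 0 each marker sits at its local offset mapped through the
    untwisted chain of joint origins."""
    markers, hom = forward_kinematics(fixture_cm, np.zeros(fixture_cm.nq))
    # frame rotations are all identity at q = 0
    np.testing.assert_allclose(hom[:, :3, :3],
                               np.tile(np.eye(3), (fixture_cm.nq + 1, 1, 1)),
                               atol=1e-14)
    expected = (hom[fixture_cm.marker_frame, :3, 3]
                + fixture_cm.marker_local)
    np.testing.assert_allclose(markers, expected, atol=1e-14)


def test_unknown_marker_segment_rejected():
    model = planar_fixture_model()
    model.markers[0].segment = "does_not_exist"
    with pytest.raises(ModelValidationError):
        model.validate()


# ------------------------------------------------- moment arms / geometry
@pytest.mark.parametrize("builder", [planar_fixture_model, arm_model])
def test_moment_arms_match_finite_differences(builder):
    """R = -dl/dq against central differences, 100 random postures."""
    cm = CompiledModel(builder())
    qs = random_configurations(cm, 100, seed=1)
    _, dl, _ = musculotendon_geometry(cm, qs)
    eps = 1e-6
    for j in range(cm.nq):
        dq = np.zeros(cm.nq)
        dq[j] = eps
        lp, _, _ = musculotendon_geometry(cm, qs + dq)
        lm, _, _ = musculotendon_geometry(cm, qs - dq)
        fd = (lp - lm) / (2 * eps)
        assert np.abs(fd - dl[:, :, j]).max() < 1e-6


def test_single_segment_path_has_constant_length_and_zero_arms():
    model = planar_fixture_model()
    # re-anchor one muscle entirely on the forearm
    mus = model.muscles[0]
    for p in mus.path:
        p.segment = "forearm"
    cm = CompiledModel(model)
    qs = random_configurations(cm, 20, seed=2)
    l, dl, _ = musculotendon_geometry(cm, qs)
    assert np.ptp(l[:, 0]) < 1e-14
    assert np.abs(dl[:, 0, :]).max() < 1e-14


def test_elbow_muscle_has_zero_shoulder_moment_arm(arm_cm):
    """Muscles crossing only the elbow produce no shoulder moment."""
    names = arm_cm.model.muscle_names
    i = names.index("brachialis")
    qs = random_configurations(arm_cm, 25, seed=3)
    R = moment_arms(arm_cm, qs)
    assert np.abs(R[:, i, :3]).max() < 1e-14
    assert np.abs(R[:, i, 3]).min() > 1e-3


# ----------------------------------------------------------- Hill muscle
def test_hill_force_normalization_anchors(fixture_cm):
    cm = fixture_cm
    l_iso = cm.l_ts + cm.l_opt          # fiber at optimal length
    zero_v = np.zeros(cm.n_muscles)
    f_max = hill_force(cm, np.ones(cm.n_muscles), l_iso, zero_v)
    np.testing.assert_allclose(f_max, cm.f_iso_max, rtol=1e-12)
    f_passive = hill_force(cm, np.zeros(cm.n_muscles), l_iso, zero_v)
    np.testing.assert_allclose(f_passive, 0.0, atol=1e-12)


def test_hill_force_at_max_shortening_is_passive_only(fixture_cm):
    cm = fixture_cm
    l_iso = cm.l_ts + cm.l_opt
    v = -cm.v_max * cm.l_opt            # normalized velocity -1
    f = hill_force(cm, np.ones(cm.n_muscles), l_iso, v)
    # chosen force-velocity curve hits exactly 0 at v_norm = -1
    assert np.abs(force_velocity(-1.0)) < 1e-12
    np.testing.assert_allclose(f, 0.0, atol=1e-9)


def test_hill_force_nonnegative_over_operating_range():
    rng = np.random.default_rng(5)
    a = rng.random(4000)
    ln = 0.5 + rng.random(4000)         # [0.5, 1.5]
    vn = -1 + 2 * rng.random(4000)      # [-1, 1]
    f = a * force_length(ln) * force_velocity(vn) + passive_force(ln)
    assert f.min() >= 0.0
    assert abs(force_length(1.0) - 1.0) < 1e-15
    assert abs(force_velocity(0.0) - 1.0) < 1e-15
    assert abs(passive_force(1.0)) < 1e-15


# ---------------------------------------------------- activation dynamics
def test_activation_fixed_point_and_rates(fixture_cm):
    cm = fixture_cm
    e = 0.4 * np.ones(cm.n_muscles)
    assert np.abs(activation_rate(cm, e, e)).max() < 1e-12
    up = activation_rate(cm, np.zeros(cm.n_muscles), np.ones(cm.n_muscles))
    np.testing.assert_allclose(up, 1.0 / cm.tau_act, rtol=1e-3)


def test_activation_step_response_time_constant(fixture_cm):
    """Time to 63.2% of a step matches tau_act within 5% at dt = 1 ms."""
    cm = fixture_cm
    dt = 1e-3
    a = np.zeros(cm.n_muscles)
    e = np.ones(cm.n_muscles)
    t, target = 0.0, 1.0 - np.exp(-1.0)
    crossing = np.full(cm.n_muscles, np.nan)
    for _ in range(400):
        a = a + dt * activation_rate(cm, a, e)
        t += dt
        newly = (a >= target) & np.isnan(crossing)
        crossing[newly] = t
    assert np.all(np.abs(crossing - cm.tau_act) / cm.tau_act < 0.05)


def test_activation_stays_in_unit_interval(fixture_cm):
    cm = fixture_cm
    rng = np.random.default_rng(11)
    a = rng.random(cm.n_muscles)
    for k in range(500):
        e = rng.random(cm.n_muscles)
        a = a + 1e-3 * activation_rate(cm, a, e)
        assert np.all(a >= -1e-12) and np.all(a <= 1 + 1e-12)


# ------------------------------------------------------- rigid-body oracle
def _newton_euler_oracle(model: MusculoskeletalModel, q, qd, qdd, gravity):
    """Independent textbook inverse dynamics (non-batched, explicit)."""
    frames = {"ground": (np.eye(3), np.zeros(3))}
    kin = {"ground": (np.zeros(3), np.zeros(3), np.zeros(3))}  # w, dw, a_o
    axes = {}
    for j, joint in enumerate(model.joints):
        Rp, op = frames[joint.parent]
        w_p, dw_p, a_p = kin[joint.parent]
        centre = op + Rp @ np.asarray(joint.origin)
        axis = Rp @ (np.asarray(joint.axis, float)
                     / np.linalg.norm(joint.axis))
        r = centre - op
        a_c = a_p + np.cross(dw_p, r) + np.cross(w_p, np.cross(w_p, r))
        w = w_p + qd[j] * axis
        dw = dw_p + qdd[j] * axis + np.cross(w_p, qd[j] * axis)
        R = Rp @ Rotation.from_rotvec(
            (np.asarray(joint.axis) / np.linalg.norm(joint.axis))
            * q[j]).as_matrix()
        frames[joint.name] = (R, centre)
        kin[joint.name] = (w, dw, a_c)
        axes[joint.name] = (axis, centre)
    tau = np.zeros(len(model.joints))
    joint_names = [j.name for j in model.joints]
    ancestors = {}
    for j, joint in enumerate(model.joints):
        chain = []
        f = joint.name
        while f != "ground":
            chain.append(f)
            f = next(jj.parent for jj in model.joints if jj.name == f)
        ancestors[joint.name] = chain
    for seg in model.segments:
        if seg.mass <= 0:
            continue
        R, o = frames[seg.frame]
        w, dw, a_o = kin[seg.frame]
        com = o + R @ np.asarray(seg.com)
        rc = com - o
        a_com = a_o + np.cross(dw, rc) + np.cross(w, np.cross(w, rc))
        f_b = seg.mass * (a_com - gravity)
        I_w = R @ np.diag(seg.inertia) @ R.T
        n_b = I_w @ dw + np.cross(w, I_w @ w)
        for jname in ([] if seg.frame == "ground"
                      else ancestors[seg.frame]):
            axis, centre = axes[jname]
            mom = n_b + np.cross(com - centre, f_b)
            tau[joint_names.index(jname)] += axis @ mom
    return tau


@pytest.mark.parametrize("builder", [planar_fixture_model, arm_model])
def test_forward_dynamics_against_unit_acceleration_oracle(builder):
    """qdd from forward_dynamics solves M qdd = tau - nle with M built
    column-by-column from unit-acceleration inverse dynamics."""
    model = builder()
    cm = CompiledModel(model)
    rng = np.random.default_rng(13)
    g = cm.gravity
    for _ in range(50):
        q = random_configurations(cm, 1, seed=rng.integers(1 << 30))[0]
        if cm.nq == 4 and abs(q[1]) < 0.35:
            # keep away from the zero-elevation axis alignment, where
            # the mass matrix conditioning (~1e6) makes an absolute
            # 1e-8 rad/s^2 comparison meaningless in double precision
            q[1] = q[1] - 0.75
        qd = 0.5 * rng.standard_normal(cm.nq)
        a = rng.random(cm.n_muscles)
        x = np.concatenate([q, qd, a])
        u = rng.random(cm.n_muscles)
        xdot = forward_dynamics(cm, x, u)
        qdd = xdot[cm.nq:2 * cm.nq]
        # oracle: M columns via unit accelerations (gravity off), nle via
        # zero-acceleration sweep (gravity on)
        nle = _newton_euler_oracle(model, q, qd, np.zeros(cm.nq), g)
        M = np.empty((cm.nq, cm.nq))
        for k in range(cm.nq):
            e = np.zeros(cm.nq)
            e[k] = 1.0
            M[:, k] = _newton_euler_oracle(model, q, qd, e, g) - nle
        tau, _ = muscle_torques(cm, q, qd, a)
        qdd_oracle = np.linalg.solve(M, tau - nle)
        # absolute 1e-8 rad/s^2 at physiological accelerations; random
        # postures far outside the calibrated workspace can blow up the
        # passive forces (accelerations ~1e5), where only the relative
        # agreement is meaningful
        tol = 1e-8 * max(1.0, np.abs(qdd_oracle).max() / 100.0)
        assert np.abs(qdd - qdd_oracle).max() < tol


def test_muscle_torque_shape_and_sign(arm_cm):
    """19 non-negative muscle forces map through a 4x19 arm matrix."""
    q = random_configurations(arm_cm, 1, seed=21)[0]
    qd = np.zeros(arm_cm.nq)
    a = 0.5 * np.ones(arm_cm.n_muscles)
    tau, forces = muscle_torques(arm_cm, q, qd, a)
    assert tau.shape == (4,)
    assert forces.shape == (19,)
    assert np.all(forces >= 0)
    R = moment_arms(arm_cm, q)
    np.testing.assert_allclose(tau, R.T @ forces, atol=1e-12)


def test_equilibrium_without_forces(fixture_model):
    """No gravity, no velocity, no activation, slack muscles: qdd = 0."""
    model = planar_fixture_model()
    model.gravity = (0.0, 0.0, 0.0)
    for mus in model.muscles:
        mus.l_ts = 1e-4  # fibers far below optimal: no passive force
        mus.l_opt = 10.0
    cm = CompiledModel(model)
    x = np.concatenate([[0.4, 0.8], np.zeros(2), np.zeros(6)])
    xdot = forward_dynamics(cm, x, np.zeros(6))
    assert np.abs(xdot[2:4]).max() < 1e-10


def test_energy_conservation_unforced(fixture_model):
    """Zero activation and passive force: mechanical energy constant to
    1e-5 J over 1 s at dt = 1 ms."""
    model = planar_fixture_model()
    for mus in model.muscles:
        mus.l_ts = 1e-4
        mus.l_opt = 10.0
    cm = CompiledModel(model)

    def energy(x):
        q, qd = x[:2], x[2:4]
        M = mass_matrix(cm, q)
        frames = cm.frames(q)
        from myomhe.model.dynamics import _body_jacobians
        com_w, _, _, _ = _body_jacobians(cm, frames)
        pot = -np.sum(cm.body_mass * (com_w @ cm.gravity))
        return 0.5 * qd @ M @ qd + pot

    x = np.concatenate([[0.4, 0.9], [0.3, -0.5], np.zeros(6)])
    e0 = energy(x)
    for _ in range(1000):
        x = integrate_interval(cm, x, np.zeros(6), 1e-3, 1)
    assert abs(energy(x) - e0) < 1e-5


# ---------------------------------------------------------- integration
def test_rk4_zero_time_is_identity(fixture_cm):
    x = np.concatenate([[0.3, 0.9], [0.1, -0.2], 0.2 * np.ones(6)])
    u = 0.3 * np.ones(6)
    out = integrate_interval(fixture_cm, x, u, 1e-12, 1)
    np.testing.assert_allclose(out, x, atol=1e-9)


def test_rk4_fourth_order_convergence(fixture_cm):
    """Richardson: halving the step shrinks the error ~16x."""
    x = np.concatenate([[0.3, 0.9], [0.5, -0.4], 0.3 * np.ones(6)])
    u = 0.4 * np.ones(6)
    dt = 0.02
    fine = integrate_interval(fixture_cm, x, u, dt, 32)
    e1 = np.abs(integrate_interval(fixture_cm, x, u, dt, 1) - fine).max()
    e2 = np.abs(integrate_interval(fixture_cm, x, u, dt, 2) - fine).max()
    ratio = e1 / e2
    assert 8.0 < ratio < 40.0


def test_rk4_matches_adaptive_integrator(fixture_cm):
    """10 ms interval against scipy RK45 at tight tolerance."""
    cm = fixture_cm
    x0 = np.concatenate([[0.3, 0.9], [0.5, -0.4], 0.3 * np.ones(6)])
    u = 0.4 * np.ones(6)
    out = integrate_interval(cm, x0, u, 0.01, 8)
    sol = solve_ivp(lambda t, x: forward_dynamics(cm, x, u), (0, 0.01), x0,
                    rtol=1e-11, atol=1e-12, method="RK45")
    assert np.abs(out - sol.y[:, -1]).max() < 1e-6


def test_fast_kernel_matches_reference_path(arm_cm):
    """Compiled batched dynamics equals the numpy implementation, for
    real inputs and under complex-step perturbation."""
    from myomhe.model._fastdyn import forward_dynamics_fast

    rng = np.random.default_rng(17)
    q = random_configurations(arm_cm, 64, seed=18)
    x = np.concatenate([q, 0.5 * rng.standard_normal((64, 4)),
                        rng.random((64, 19))], axis=1)
    u = rng.random((64, 19))
    ref = forward_dynamics(arm_cm, x, u)
    fast = forward_dynamics_fast(arm_cm, x, u)
    scale = np.maximum(1.0, np.abs(ref))
    assert (np.abs(ref - fast.real) / scale).max() < 1e-10
    xc = x.astype(complex)
    xc[:, 2] += 1e-30j
    refc = forward_dynamics(arm_cm, xc, u)
    fastc = forward_dynamics_fast(arm_cm, xc, u)
    scale = np.maximum(1e-3, np.abs(refc.imag))
    assert (np.abs(refc.imag - fastc.imag) / scale).max() < 1e-6


# ------------------------------------------------------------- model I/O
def test_yaml_roundtrip(tmp_path, fixture_model):
    path = tmp_path / "model.yaml"
    fixture_model.to_yaml(path)
    back = MusculoskeletalModel.from_yaml(path)
    assert back.content_hash() == fixture_model.content_hash()
    assert back.muscle_names == fixture_model.muscle_names


def test_arm_model_counts_and_limits(arm):
    """Flagship model: 4 DoFs, 19 muscles, 8 markers, printed limits."""
    assert arm.nq == 4
    assert arm.n_muscles == 19
    assert arm.n_markers == 8
    np.testing.assert_allclose(
        arm.joint_limits,
        [[-np.pi / 2, np.pi / 2], [-2.0, np.pi / 2],
         [-np.pi / 2, np.pi / 2], [-0.5, 2.1]])
    marker_parents = {mk.segment for mk in arm.markers}
    assert marker_parents <= {"humerus", "ulna", "radius"}
    for mus in arm.muscles:
        assert len(mus.path) >= 2
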