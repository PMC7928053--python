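"""Reference-motion generation by optimal control.

The ground-truth dataset is a dynamically consistent cyclic arm motion:
joint kinematics are imposed at the initial and final instants (and at
mid-cycle, which is what makes the cycle an actual movement), muscle
excitations drive the excitation-driven dynamics, and a least-effort
cost with optional co-contraction floors resolves the muscle redundancy.
The problem is transcribed by direct multiple shooting (the flagship
configuration uses 800 shooting intervals over 8 s, i.e. a 100 Hz node
grid) and solved with the package's Gauss-Newton SQP.

Co-contraction levels impose minimum-excitation targets {0, 0.1, 0.2,
0.3} (levels none/low/mid/high) on the triceps/biceps antagonist pair
through a one-sided quadratic penalty, producing four excitation
profiles for the same kinematic task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model.builders import (ARM_COCONTRACTION_PAIR,
                             FIXTURE_COCONTRACTION_PAIR)
from .model.kinematics import CompiledModel
from .model.muscle import hill_force, musculotendon_geometry
from .model.types import MusculoskeletalModel
from .ocp import MultipleShootingNLP, SqpOptions, solve_sqp

#: minimum-excitation targets of the four co-contraction levels
COCONTRACTION_TARGETS = {"none": 0.0, "low": 0.1, "mid": 0.2, "high": 0.3}

#: named boundary postures of the default cyclic task per model: the
#: cycle starts and ends at rest in ``q_start`` and passes through
#: ``q_mid`` at half-period (elbow flexion-extension with modest
#: shoulder elevation for the arm model)
DEFAULT_TASKS = {
    "arm4d19": {"q_start": (0.1, -0.35, 0.1, 0.6),
                "q_mid": (0.2, -0.57, 0.16, 1.08)},
    "planar_arm": {"q_start": (0.2, 0.5), "q_mid": (0.64, 0.98)},
}

DEFAULT_PAIRS = {
    "arm4d19": ARM_COCONTRACTION_PAIR,
    "planar_arm": FIXTURE_COCONTRACTION_PAIR,
}


@dataclass
class ReferenceWeights:
    """Cost weights of the reference OCP (all config entries)."""

    control: float = 100.0       # squared excitations
    velocity: float = 1.0        # squared joint velocities
    activation: float = 1.0      # squared activation states
    cocontraction: float = 1e4   # one-sided floor on the antagonist pair
    tonus: float = 0.02          # resting excitation target of the effort
    #                              terms; keeps silent muscles strictly
    #                              inside the [0, 1] bounds
    kinematic_tracking: float = 1e3  # soft tracking of the plain-level
    #                              joint trajectory at co-contracted
    #                              levels ("same kinematics" coupling)


@dataclass
class ReferenceDataset:
    """Ground truth: states, excitations, forces, markers on a time grid.

    ``excitations`` is stored per frame; the last row duplicates the
    final interval's control so every array shares the frame count.
    """

    time: np.ndarray          # (T,) s
    q: np.ndarray             # (T, nq) rad
    qdot: np.ndarray          # (T, nq) rad/s
    activations: np.ndarray   # (T, M)
    excitations: np.ndarray   # (T, M) clean EMG envelopes
    forces: np.ndarray        # (T, M) N
    markers: np.ndarray       # (T, n_markers, 3) m
    cocontraction: str = "none"
    model_hash: str = ""
    config: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def save(self, out_dir: str | Path) -> None:
        from .io import write_reference_dataset
        write_reference_dataset(self, out_dir)

    @classmethod
    def load(cls, in_dir: str | Path) -> "ReferenceDataset":
        from .io import read_reference_dataset
        return read_reference_dataset(in_dir)


def cocontraction_indices(model: MusculoskeletalModel,
                          pair_names=None) -> np.ndarray:
    names = pair_names or DEFAULT_PAIRS.get(model.name)
    if names is None:
        raise ValueError(f"no default antagonist pair for model "
                         f"{model.name!r}; pass pair_names")
    lookup = {n: i for i, n in enumerate(model.muscle_names)}
    return np.array([lookup[n] for n in names], int)


def default_reference_options() -> SqpOptions:
    """Solver settings for reference OCP solves: moderate Levenberg
    damping and a tight feasibility-growth cap, followed by a
    feasibility polish in the callers."""
    return SqpOptions(max_iter=150, tol_feas=1e-9, tol_stat=1e-2,
                      damping=1e-4, damping_init=1e-2,
                      theta_growth=1.2, theta_growth_abs=1e-3)


def build_reference_ocp(model: MusculoskeletalModel | CompiledModel,
                        duration_s: float = 8.0, n_nodes: int = 800,
                        cocontraction_level: str = "none",
                        weights: ReferenceWeights | None = None,
                        task: dict | None = None,
                        pair_names=None,
                        q_reference: np.ndarray | None = None):
    """Transcribe the reference OCP; returns ``(nlp, z0)``.

    ``n_nodes`` counts shooting intervals, so the state grid has
    ``n_nodes + 1`` frames at spacing ``duration_s / n_nodes`` (800
    intervals over 8 s = a 100 Hz grid).
    """
    if cocontraction_level not in COCONTRACTION_TARGETS:
        raise ValueError(f"unknown co-contraction level "
                         f"{cocontraction_level!r}")
    if n_nodes < 2 or duration_s <= 0:
        raise ValueError("need n_nodes >= 2 and duration_s > 0")
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    mdl = cm.model
    w = weights or ReferenceWeights()
    task = task or DEFAULT_TASKS.get(mdl.name)
    if task is None:
        raise ValueError(f"no default task for model {mdl.name!r}; pass task")
    q_start = np.asarray(task["q_start"], float)
    q_mid = np.asarray(task["q_mid"], float)

    N = n_nodes + 1
    dt = duration_s / n_nodes
    nlp = MultipleShootingNLP(cm, N, dt, excitation_driven=True)
    nlp.set_control_penalty(w.control, target=w.tonus)
    nlp.set_velocity_penalty(w.velocity)
    nlp.set_activation_penalty(w.activation, target=w.tonus)
    # start the cycle from muscle steady state (a0 = e0) so a stream cut
    # at t = 0 carries no hidden activation transient
    nlp.set_steady_start_penalty(1e4)
    target = COCONTRACTION_TARGETS[cocontraction_level]
    if target > 0 and w.cocontraction > 0:
        idx = cocontraction_indices(mdl, pair_names)
        nlp.set_cocontraction_floor(w.cocontraction, idx, target)
    if q_reference is not None and w.kinematic_tracking > 0:
        nlp.set_q_tracking(w.kinematic_tracking, q_reference)

    nq = cm.nq
    zero_qd = np.zeros(nq)
    kin = np.arange(2 * nq)
    nlp.fix_state(0, np.concatenate([q_start, zero_qd]), kin)
    nlp.fix_state(N - 1, np.concatenate([q_start, zero_qd]), kin)
    nlp.fix_state(N // 2, q_mid, np.arange(nq))

    # deterministic initial guess: a smooth cosine cycle through the
    # imposed postures, with activations from per-node static
    # optimization and excitations from inverted activation dynamics
    t = np.linspace(0.0, duration_s, N)
    omega = 2.0 * np.pi / duration_s
    shape = 0.5 * (1.0 - np.cos(omega * t))
    dq = (q_mid - q_start)[None, :]
    q0 = q_start[None, :] + shape[:, None] * dq
    qd0 = 0.5 * omega * np.sin(omega * t)[:, None] * dq
    qdd0 = 0.5 * omega ** 2 * np.cos(omega * t)[:, None] * dq
    floor = COCONTRACTION_TARGETS[cocontraction_level]
    floor_idx = (cocontraction_indices(mdl, pair_names)
                 if floor > 0 else np.zeros(0, int))
    a0 = static_activation_guess(cm, q0, qd0, qdd0,
                                 tonus=max(w.tonus, 0.02),
                                 floor=floor, floor_idx=floor_idx)
    u0 = invert_activation_dynamics(cm, a0, dt)
    x0 = np.concatenate([q0, qd0, a0], axis=1)
    return nlp, nlp.pack(x0, u0)


def _polish_feasibility(nlp: MultipleShootingNLP, res,
                        target: float = 1e-9):
    """Drive residual defects below ``target`` from a near-solution via
    minimum-norm Newton restoration; returns the better result."""
    import dataclasses

    from .ocp import newton_restoration

    if res.feas <= target or res.feas > 1e-3:
        return res
    z, feas = newton_restoration(nlp, res.z, target=target, max_iter=12)
    if feas < res.feas:
        res = dataclasses.replace(res, z=z, feas=feas)
    return res


def static_activation_guess(cm: CompiledModel, q: np.ndarray,
                            qd: np.ndarray, qdd: np.ndarray,
                            tonus: float = 0.02, floor: float = 0.0,
                            floor_idx: np.ndarray | None = None,
                            reg: float = 10.0) -> np.ndarray:
    """Per-node static-optimization activations realizing (q, qd, qdd).

    Muscle torque is linear in activation, tau = A a + b, so each node is
    a Tikhonov-regularized least-squares solve clipped into (0, 1); used
    only to initialize the reference OCP.
    """
    from .model.dynamics import inverse_dynamics
    from .model.muscle import force_length, force_velocity, passive_force

    tau_req = inverse_dynamics(cm, q, qd, qdd)               # (T, nq)
    l_mt, dl_dq, v_mt = musculotendon_geometry(cm, q, qd)
    l_n = (l_mt - cm.l_ts) / cm.l_opt
    v_n = v_mt / (cm.l_opt * cm.v_max)
    gain = cm.f_iso_max * force_length(l_n) * force_velocity(v_n)
    fp = cm.f_iso_max * passive_force(l_n)
    A = -dl_dq.swapaxes(-1, -2) * gain[..., None, :]         # (T, nq, M)
    b = -np.einsum("...mq,...m->...q", dl_dq, fp)
    T, nq = tau_req.shape
    M = cm.n_muscles
    from scipy.optimize import nnls

    a = np.empty((T, M))
    eye = np.sqrt(reg) * np.eye(M)
    target = np.full(M, tonus)
    if floor > 0 and floor_idx is not None and len(floor_idx):
        target = target.copy()
        target[floor_idx] = floor
    for k in range(T):
        lhs = np.vstack([A[k], eye])
        rhs = np.concatenate([tau_req[k] - b[k], np.sqrt(reg) * target])
        sol, _ = nnls(lhs, rhs)
        a[k] = np.clip(sol, tonus / 2.0, 0.9)
    if floor > 0 and floor_idx is not None and len(floor_idx):
        a[:, floor_idx] = np.maximum(a[:, floor_idx], floor)
    return a


def invert_activation_dynamics(cm: CompiledModel, a: np.ndarray,
                               dt: float) -> np.ndarray:
    """Excitations that roughly reproduce an activation trajectory."""
    da = np.diff(a, axis=0) / dt
    tau = np.where(da >= 0, cm.tau_act, cm.tau_deact)
    return np.clip(a[:-1] + tau * da, 1e-3, 1.0)


def dataset_from_solution(cm: CompiledModel, nlp: MultipleShootingNLP,
                          z: np.ndarray, cocontraction_level: str,
                          config: dict | None = None) -> ReferenceDataset:
    x = nlp.states(z)
    u = nlp.controls(z)
    nq = cm.nq
    q, qd, a = x[:, :nq], x[:, nq:2 * nq], x[:, 2 * nq:]
    exc = np.vstack([u, u[-1]])
    time = np.arange(nlp.N) * nlp.dt
    forces = trajectory_forces(cm, q, qd, a)
    markers = cm.marker_positions(q)
    return ReferenceDataset(time=time, q=q, qdot=qd, activations=a,
                            excitations=exc, forces=forces, markers=markers,
                            cocontraction=cocontraction_level,
                            model_hash=cm.model.content_hash(),
                            config=config or {})


def solve_reference(model: MusculoskeletalModel | CompiledModel,
                    duration_s: float = 8.0, n_nodes: int = 800,
                    cocontraction_level: str = "none",
                    weights: ReferenceWeights | None = None,
                    task: dict | None = None, pair_names=None,
                    options: SqpOptions | None = None,
                    warm_start: np.ndarray | None = None):
    """Solve the reference OCP; returns ``(ReferenceDataset, SqpResult)``.

    Raises ``RuntimeError`` with the residual constraint violation if the
    solver fails to reach feasibility.
    """
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    nlp, z0 = build_reference_ocp(cm, duration_s, n_nodes,
                                  cocontraction_level, weights, task,
                                  pair_names)
    if warm_start is not None:
        z0 = warm_start
    opts = options or default_reference_options()
    res = solve_sqp(nlp, z0, opts)
    res = _polish_feasibility(nlp, res)
    if res.feas > 3e-8:
        raise RuntimeError(
            f"reference OCP did not converge: {res.message} "
            f"(feasibility {res.feas:.2e}, stationarity {res.stat:.2e})")
    config = {"duration_s": duration_s, "n_nodes": n_nodes,
              "cocontraction": cocontraction_level,
              "weights": vars(weights or ReferenceWeights())}
    ds = dataset_from_solution(cm, nlp, res.z, cocontraction_level, config)
    return ds, res


def solve_reference_family(model: MusculoskeletalModel | CompiledModel,
                           levels=("none", "low", "mid", "high"),
                           duration_s: float = 8.0, n_nodes: int = 800,
                           weights: ReferenceWeights | None = None,
                           task: dict | None = None, pair_names=None,
                           options: SqpOptions | None = None) -> dict:
    """Solve the reference OCP at several co-contraction levels.

    The levels form a natural homotopy in the floor target, so each
    level is warm-started from the previous solution (the plain
    least-effort problem is solved cold first).  Returns a dict
    ``level -> (ReferenceDataset, SqpResult)`` restricted to ``levels``.
    """
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    order = [lv for lv in ("none", "low", "mid", "high")]
    want = set(levels)
    top = max(order.index(lv) for lv in want)
    out = {}
    warm = None
    q_none = None
    for lv in order[: top + 1]:
        nlp, z0 = build_reference_ocp(cm, duration_s, n_nodes, lv, weights,
                                      task, pair_names,
                                      q_reference=q_none)
        opts = options or default_reference_options()
        res = solve_sqp(nlp, warm if warm is not None else z0, opts)
        res = _polish_feasibility(nlp, res)
        if res.feas > 3e-8:
            raise RuntimeError(
                f"reference OCP (level {lv}) did not converge: "
                f"{res.message} (feasibility {res.feas:.2e})")
        warm = res.z
        if q_none is None:
            q_none = nlp.states(res.z)[:, : cm.nq].copy()
        if lv in want:
            config = {"duration_s": duration_s, "n_nodes": n_nodes,
                      "cocontraction": lv,
                      "weights": vars(weights or ReferenceWeights())}
            out[lv] = (dataset_from_solution(cm, nlp, res.z, lv, config),
                       res)
    return out


def trajectory_forces(cm: CompiledModel, q: np.ndarray, qd: np.ndarray,
                      a: np.ndarray) -> np.ndarray:
    """Hill forces (T, M) along a state trajectory."""
    l_mt, _, v_mt = musculotendon_geometry(cm, q, qd)
    return hill_force(cm, a, l_mt, v_mt)


def extract_muscle_forces(model: MusculoskeletalModel | CompiledModel,
                          dataset: ReferenceDataset) -> np.ndarray:
    """Recompute per-frame muscle forces of a dataset from its states."""
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    return trajectory_forces(cm, dataset.q, dataset.qdot,
                             dataset.activations)
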