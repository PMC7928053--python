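"""Moving-horizon estimation of muscle forces from EMG and markers.

The estimator repeatedly solves a small tracking optimal-control problem
over the most recent window of measurements.  Each window is a direct
multiple-shooting NLP whose running cost tracks marker positions (weight
``w_markers``) and, depending on the variant, tracks the EMG envelopes
(weight ``w_emg``) or minimizes squared excitations.  When a new
measurement arrives the window shifts forward by one frame, the first
state is constrained to equal the second state of the previous solution
(which is what makes the chained estimates dynamically consistent), the
previous solution is shifted one node as a warm start, and the NLP is
re-solved.  The stored estimate of every step is the first state and
control of the window.

Two model formulations are supported: excitation-driven (states include
the muscle activations; controls are neural excitations) and
activation-driven (activations are controls; the electromechanical delay
between EMG and activation is compensated by shifting the EMG stream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from time import perf_counter

import numpy as np

from .model.dynamics import integrate_interval
from .model.kinematics import CompiledModel
from .model.types import MusculoskeletalModel
from .ocp import (ActiveSet, BufferingError, MultipleShootingNLP,
                  SqpOptions, newton_restoration, solve_sqp)
from .reference import ReferenceDataset, trajectory_forces

#: printed marker-tracking weights of the two EMG-tracking cost variants
VARIANT_MARKER_WEIGHTS = {"track_emg_high_marker": 1e9,
                          "track_emg_low_marker": 1e7,
                          "min_excitation": 1e9}


@dataclass
class CostWeights:
    """Weights of the window running cost.

    ``variant`` selects among EMG + marker tracking with high or low
    marker weight, or marker tracking with least-squared excitations.
    """

    variant: str = "track_emg_high_marker"
    w_markers: float | None = None   # default: per-variant printed value
    w_emg: float = 1e3
    w_exc_min: float = 10.0          # squared-excitation weight (variant 3)
    w_state_reg: float = 1e-2        # on joint velocities only
    w_control_reg: float = 1e-2
    w_activation_reg: float = 1e-4   # conditioning term: the activation
    #                                  states are otherwise cost-free and
    #                                  their unobservable directions leave
    #                                  the window NLP singular

    def __post_init__(self):
        if self.variant not in VARIANT_MARKER_WEIGHTS:
            raise ValueError(f"unknown cost variant {self.variant!r}")
        if self.w_markers is None:
            self.w_markers = VARIANT_MARKER_WEIGHTS[self.variant]

    @property
    def tracks_emg(self) -> bool:
        return self.variant != "min_excitation"


@dataclass
class MeasurementFrame:
    """One time-stamped sample of tracked data."""

    timestamp: float
    markers: np.ndarray   # (n_markers, 3) m; NaN rows = occluded
    emg: np.ndarray       # (n_muscles,) in [0, 1]


@dataclass
class MeasurementStream:
    """Uniformly sampled measurement sequence."""

    time: np.ndarray      # (T,)
    markers: np.ndarray   # (T, n_markers, 3)
    emg: np.ndarray       # (T, n_muscles)

    def __post_init__(self):
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def frame(self, k: int) -> MeasurementFrame:
        return MeasurementFrame(float(self.time[k]), self.markers[k],
                                self.emg[k])

    @classmethod
    def from_reference(cls, ds: ReferenceDataset) -> "MeasurementStream":
        """Noiseless measurements of a reference dataset."""
        return cls(time=ds.time.copy(), markers=ds.markers.copy(),
                   emg=ds.excitations.copy())


def subsample_stream(stream: MeasurementStream, k: int) -> MeasurementStream:
    """Keep every k-th frame starting at frame 0 (simulated real time)."""
    if k < 1 or int(k) != k:
        raise ValueError("subsample factor must be an integer >= 1")
    k = int(k)
    return MeasurementStream(time=stream.time[::k].copy(),
                             markers=stream.markers[::k].copy(),
                             emg=stream.emg[::k].copy())


def delay_emg(stream: MeasurementStream, delay_s: float
              ) -> MeasurementStream:
    """Shift the EMG channels later in time by the electromechanical
    delay (integer frames, nearest); the leading frames repeat the first
    sample."""
    shift = int(round(delay_s / stream.dt))
    if shift <= 0:
        return stream
    emg = np.vstack([np.repeat(stream.emg[:1], shift, axis=0),
                     stream.emg[:-shift]])
    return MeasurementStream(time=stream.time.copy(),
                             markers=stream.markers.copy(), emg=emg)


@dataclass
class MheProblem:
    """Configuration of the moving-horizon estimator."""

    window: int = 7                      # frames per window
    formulation: str = "excitation_driven"
    weights: CostWeights = field(default_factory=CostWeights)
    n_substeps: int = 1                  # RK4 substeps per interval
    max_iter: int = 25                   # SQP iterations per window
    tol_constraint: float = 1e-7

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window must span at least 2 frames")
        if self.formulation not in ("excitation_driven",
                                    "activation_driven"):
            raise ValueError(f"unknown formulation {self.formulation!r}")

    @property
    def excitation_driven(self) -> bool:
        return self.formulation == "excitation_driven"


@dataclass
class EstimationResult:
    """Chained per-frame estimates of one MHE run."""

    time: np.ndarray         # (S,)
    states: np.ndarray       # (S, nx)
    controls: np.ndarray     # (S, nu)
    forces: np.ndarray       # (S, n_muscles) N
    converged: np.ndarray    # (S,) bool per window solve
    iterations: np.ndarray   # (S,)
    solve_seconds: np.ndarray  # (S,) informational timing log
    config: dict = field(default_factory=dict)

    @property
    def convergence_rate(self) -> float:
        return float(np.mean(self.converged))

    @property
    def achieved(self) -> bool:
        """More than 90% of the window solves converged."""
        return self.convergence_rate > 0.90

    def q(self, nq: int) -> np.ndarray:
        return self.states[:, :nq]

    def qdot(self, nq: int) -> np.ndarray:
        return self.states[:, nq:2 * nq]


class MovingHorizonEstimator:
    """Stateful MHE loop over a measurement stream."""

    def __init__(self, model: MusculoskeletalModel | CompiledModel,
                 problem: MheProblem):
        self.cm = (model if isinstance(model, CompiledModel)
                   else CompiledModel(model))
        self.problem = problem
        self.nlp: MultipleShootingNLP | None = None
        self._buffer: list[MeasurementFrame] = []
        self._z = None
        self._active_set: ActiveSet | None = None
        self._next_x0 = None
        self._last_ok = True
        self._emg_seen: list[np.ndarray] = []

    # ------------------------------------------------------------ building
    def _build_nlp(self, dt: float) -> MultipleShootingNLP:
        p = self.problem
        w = p.weights
        nlp = MultipleShootingNLP(self.cm, p.window, dt,
                                  excitation_driven=p.excitation_driven,
                                  n_substeps=p.n_substeps)
        if w.w_state_reg > 0:
            nlp.set_velocity_penalty(w.w_state_reg)
        if p.excitation_driven and w.w_activation_reg > 0:
            nlp.set_activation_penalty(w.w_activation_reg)
        if w.tracks_emg:
            nlp.set_control_penalty(w.w_control_reg)
        else:
            nlp.set_control_penalty(w.w_exc_min)
        return nlp

    def _set_window_cost(self, frames: list[MeasurementFrame]) -> None:
        w = self.problem.weights
        markers = np.stack([f.markers for f in frames])
        self.nlp.set_marker_tracking(w.w_markers, markers)
        if w.tracks_emg:
            emg = np.stack([f.emg for f in frames[:-1]])
            self.nlp.set_emg_tracking(w.w_emg, emg)

    def _initial_guess(self, frames: list[MeasurementFrame]) -> np.ndarray:
        """IK-based first-window guess: per-frame marker fit for q,
        finite differences for velocities, and activations obtained by
        integrating the activation dynamics under the measured EMG (so
        the guess starts dynamics-consistent in the muscle states)."""
        from .model.muscle import activation_rate

        markers = np.stack([f.markers for f in frames])
        q = inverse_kinematics(self.cm, markers)
        dt = self.nlp.dt
        qd = np.gradient(q, dt, axis=0)
        parts = [q, qd]
        emg = np.clip(np.stack([f.emg for f in frames]), 1e-3, 1.0)
        if self.problem.excitation_driven:
            a = np.empty_like(emg)
            a[0] = emg[0]
            h = dt / max(1, 4 * self.problem.n_substeps)
            for k in range(len(emg) - 1):
                ak = a[k]
                for _ in range(max(1, 4 * self.problem.n_substeps)):
                    ak = np.clip(ak + h * activation_rate(self.cm, ak,
                                                          emg[k]), 0, 1)
                a[k + 1] = ak
            parts.append(a)
        x0 = np.concatenate(parts, axis=1)
        u0 = emg[:-1]
        return self.nlp.pack(x0, u0)

    # ------------------------------------------------------------- stepping
    def _solve(self, cold: bool = False
               ) -> tuple[np.ndarray, np.ndarray, bool, int, float]:
        p = self.problem
        t0 = perf_counter()
        # min-excitation leaves a non-vanishing marker residual at its
        # optimum (it trades marker fit against effort), so the Gauss-
        # Newton model needs a persistent Levenberg floor there
        if p.weights.tracks_emg:
            floor, init, extra = 1e-7, 1e-7, 0
        else:
            # the min-excitation cost leaves broad weak-curvature
            # subspaces; undamped Gauss-Newton steps there are garbage
            floor, init, extra = 1e-2, 1e-1, 2
        if cold:
            # the first window starts from an IK guess with sizable
            # defects; heavier initial damping keeps the Gauss-Newton
            # steps inside the linearization's validity
            opts = SqpOptions(max_iter=max(60, 2 * p.max_iter) + extra,
                              tol_feas=p.tol_constraint, tol_stat=1e-2,
                              damping=floor, damping_init=max(1e-2, init),
                              theta_growth=1.2, theta_growth_abs=1e-3)
        else:
            opts = SqpOptions(max_iter=p.max_iter + extra,
                              tol_feas=p.tol_constraint, tol_stat=1e-2,
                              damping=floor, damping_init=init,
                              theta_growth=1.2, theta_growth_abs=1e-3,
                              max_active_set_passes=6)
        res = solve_sqp(self.nlp, self._z, opts,
                        active_set=self._active_set)
        iters = res.iterations
        z_best = res.z
        feas = res.feas
        if feas > 1e-3:
            # large residual violations: grind them down with a heavily
            # damped restoration solve first
            restore = solve_sqp(
                self.nlp, z_best,
                SqpOptions(max_iter=12, tol_feas=p.tol_constraint,
                           tol_stat=1e12, damping=1.0, damping_init=10.0,
                           track_best_feasibility=True),
                active_set=res.active_set)
            iters += restore.iterations
            if restore.feas < feas:
                z_best, feas = restore.z, restore.feas
        proj_dist = 0.0
        if p.tol_constraint < feas <= 5e-2:
            # small violations: project onto the dynamics manifold
            # (minimum-norm Newton restoration) so the stored estimates
            # stay dynamically consistent
            z_proj, feas_proj = newton_restoration(
                self.nlp, z_best, target=p.tol_constraint)
            if feas_proj < feas:
                proj_dist = float(np.abs(z_proj - z_best).max())
                z_best, feas = z_proj, feas_proj
        elapsed = perf_counter() - t0
        # converged = feasible, and any projection was a small correction
        ok = bool(feas <= 1e-6 and proj_dist <= 0.05)
        if ok:
            self._z = z_best
            self._active_set = res.active_set
        x = self.nlp.states(self._z)
        u = self.nlp.controls(self._z)
        return x, u, ok, iters, elapsed

    def _integrate_emg_history(self, history: np.ndarray) -> np.ndarray:
        """Activation at the end of an EMG history (T, nu), obtained by
        integrating the activation ODE from the history's first sample;
        the initial condition is forgotten within ~3 deactivation time
        constants."""
        from .model.muscle import activation_rate

        a = np.clip(history[0], 1e-3, 1.0)
        if len(history) < 2:
            return a
        h = self.nlp.dt / max(1, 4 * self.problem.n_substeps)
        for k in range(len(history) - 1):
            for _ in range(max(1, 4 * self.problem.n_substeps)):
                a = np.clip(a + h * activation_rate(self.cm, a, history[k]),
                            0.0, 1.0)
        return a

    def start(self, frames: list[MeasurementFrame], dt: float,
              emg_history: np.ndarray | None = None):
        """First full-window solve (no initial-state constraint).

        With an ``emg_history`` (the EMG samples preceding and including
        the window start) and an EMG-tracking variant, the initial
        activation state is fixed to the history-integrated value: the
        window itself carries almost no information about it.
        """
        if len(frames) != self.problem.window:
            raise BufferingError(
                f"need {self.problem.window} frames to start, "
                f"got {len(frames)}")
        self.nlp = self._build_nlp(dt)
        self._buffer = list(frames)
        self._emg_seen = [f.emg.copy() for f in frames]
        self._set_window_cost(frames)
        self._z = self._initial_guess(frames)
        if (emg_history is not None and len(emg_history) >= 1
                and self.problem.excitation_driven
                and self.problem.weights.tracks_emg):
            a0 = self._integrate_emg_history(emg_history)
            self.nlp.fix_state(0, a0, np.arange(2 * self.cm.nq, self.nlp.nx))
            x = self.nlp.states(self._z)
            x[0, 2 * self.cm.nq:] = a0
            self._z = self.nlp.pack(x, self.nlp.controls(self._z))
        self._active_set = None
        x, u, ok, iters, secs = self._solve(cold=True)
        self._next_x0 = x[1].copy()
        self._last_ok = ok
        return x[0], u[0], ok, iters, secs

    def step(self, frame: MeasurementFrame):
        """Shift the window by one frame and re-solve (Algorithm line:
        discard oldest, impose first state, warm start, solve)."""
        if self.nlp is None:
            raise BufferingError("call start() with a full window first")
        self._buffer = self._buffer[1:] + [frame]
        self._emg_seen.append(frame.emg.copy())
        if not self._last_ok:
            # re-anchor after a failed solve: restarting the chain from a
            # fresh IK-based window keeps one bad window from poisoning
            # every subsequent initial-state constraint; the initial
            # activations come from the integrated EMG history
            self.release_initial_state()
            self._set_window_cost(self._buffer)
            self._z = self._initial_guess(self._buffer)
            if (self.problem.excitation_driven
                    and self.problem.weights.tracks_emg):
                start_idx = len(self._emg_seen) - self.problem.window
                hist = np.asarray(
                    self._emg_seen[max(0, start_idx - 18):start_idx + 1])
                if len(hist) > 1:
                    a0 = self._integrate_emg_history(hist)
                    self.nlp.fix_state(
                        0, a0, np.arange(2 * self.cm.nq, self.nlp.nx))
                    xg = self.nlp.states(self._z)
                    xg[0, 2 * self.cm.nq:] = a0
                    self._z = self.nlp.pack(xg, self.nlp.controls(self._z))
            self._active_set = None
            x, u, ok, iters, secs = self._solve(cold=True)
            self._next_x0 = x[1].copy()
            self._last_ok = ok
            return x[0], u[0], ok, iters, secs
        self._set_window_cost(self._buffer)
        self.nlp.fix_state(0, self._next_x0)
        x_prev = self.nlp.states(self._z)
        u_prev = self.nlp.controls(self._z)
        # shift one node and predict the new tail state by integrating
        # the model under the held last control (defect-free warm start)
        x_tail = integrate_interval(self.cm, x_prev[-1], u_prev[-1],
                                    self.nlp.dt, self.nlp.n_substeps,
                                    self.problem.excitation_driven,
                                    check=False)
        x_ws = np.vstack([x_prev[1:], x_tail[None, :]])
        u_ws = np.vstack([u_prev[1:], u_prev[-1:]])
        self._z = self.nlp.pack(x_ws, u_ws)
        x, u, ok, iters, secs = self._solve()
        if not ok:
            # keep the shifted previous solution as the fallback estimate
            x, u = x_ws, u_ws
        self._next_x0 = x[1].copy()
        self._last_ok = ok
        return x[0], u[0], ok, iters, secs

    def release_initial_state(self) -> None:
        self.nlp.release_state(0)


def inverse_kinematics(cm: CompiledModel, markers: np.ndarray,
                       q0: np.ndarray | None = None,
                       n_iter: int = 15) -> np.ndarray:
    """Damped Gauss-Newton marker fit per frame (initial-guess helper)."""
    markers = np.atleast_3d(markers)
    if markers.ndim == 3 and markers.shape[-1] != 3:
        raise ValueError("markers must be (..., n_markers, 3)")
    single = markers.ndim == 3 and markers.shape[0] == cm.n_markers
    frames = markers if not single else markers[None]
    q = np.tile(0.5 * (cm.q_lower + cm.q_upper), (len(frames), 1)) \
        if q0 is None else np.tile(np.asarray(q0, float), (len(frames), 1))
    for _ in range(n_iter):
        pos, jac = cm.marker_jacobians(q)
        res = (pos - frames).reshape(len(frames), -1)
        res = np.nan_to_num(res)
        J = jac.reshape(len(frames), -1, cm.nq)
        JtJ = np.einsum("fri,frj->fij", J, J) + 1e-8 * np.eye(cm.nq)
        Jtr = np.einsum("fri,fr->fi", J, res)
        q = q - np.linalg.solve(JtJ, Jtr[..., None])[..., 0]
        q = np.clip(q, cm.q_lower, cm.q_upper)
    return q[0] if single else q


def run_mhe(model: MusculoskeletalModel | CompiledModel,
            stream: MeasurementStream,
            problem: MheProblem | None = None) -> EstimationResult:
    """Run the full MHE loop over a measurement stream.

    In the activation-driven formulation the EMG channels are first
    shifted by the electromechanical delay so activations are compared
    with the excitation signal that produced them.
    """
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    p = problem or MheProblem()
    if len(stream) <= p.window:
        raise BufferingError(
            f"stream of {len(stream)} frames is shorter than the "
            f"window ({p.window})")
    if stream.emg.shape[1] != cm.n_muscles:
        raise ValueError(f"expected {cm.n_muscles} EMG channels, got "
                         f"{stream.emg.shape[1]}")
    if stream.markers.shape[1] != cm.n_markers:
        raise ValueError(f"expected {cm.n_markers} marker trajectories, "
                         f"got {stream.markers.shape[1]}")
    if not p.excitation_driven:
        delay = float(np.median(cm.delay))
        stream = delay_emg(stream, delay)

    est = MovingHorizonEstimator(cm, p)
    N = p.window
    first = [stream.frame(k) for k in range(N)]
    xs, us, oks, its, secs, times = [], [], [], [], [], []
    # start-up prior: streams begin at muscle steady state, so the first
    # window's initial activations are pinned to the first EMG sample
    x0, u0, ok, it, sec = est.start(first, stream.dt,
                                    emg_history=stream.emg[:1])
    xs.append(x0); us.append(u0); oks.append(ok); its.append(it)
    secs.append(sec); times.append(stream.time[0])
    for k in range(N, len(stream)):
        x0, u0, ok, it, sec = est.step(stream.frame(k))
        xs.append(x0); us.append(u0); oks.append(ok); its.append(it)
        secs.append(sec); times.append(stream.time[k - N + 1])
    xs = np.array(xs)
    us = np.array(us)
    nq = cm.nq
    act = xs[:, 2 * nq:] if p.excitation_driven else us
    forces = trajectory_forces(cm, xs[:, :nq], xs[:, nq:2 * nq], act)
    return EstimationResult(
        time=np.array(times), states=xs, controls=us, forces=forces,
        converged=np.array(oks, bool), iterations=np.array(its),
        solve_seconds=np.array(secs),
        config={"window": p.window, "formulation": p.formulation,
                "variant": p.weights.variant,
                "weights": {k: v for k, v in vars(p.weights).items()},
                "dt": stream.dt, "n_substeps": p.n_substeps})


def full_window_estimate(model: MusculoskeletalModel | CompiledModel,
                         stream: MeasurementStream,
                         weights: CostWeights | None = None,
                         formulation: str = "excitation_driven",
                         n_substeps: int = 1,
                         max_iter: int = 150) -> EstimationResult:
    """Offline baseline: one tracking NLP over the entire stream."""
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    p = MheProblem(window=len(stream), formulation=formulation,
                   weights=weights or CostWeights(),
                   n_substeps=n_substeps, max_iter=max_iter)
    if not p.excitation_driven:
        stream = delay_emg(stream, float(np.median(cm.delay)))
    est = MovingHorizonEstimator(cm, p)
    frames = [stream.frame(k) for k in range(len(stream))]
    t0 = perf_counter()
    est.nlp = est._build_nlp(stream.dt)
    est._buffer = frames
    est._set_window_cost(frames)
    est._z = est._initial_guess(frames)
    res = solve_sqp(est.nlp, est._z,
                    SqpOptions(max_iter=max_iter, tol_feas=1e-7,
                               tol_stat=1e-4))
    elapsed = perf_counter() - t0
    x = est.nlp.states(res.z)
    u = est.nlp.controls(res.z)
    u_full = np.vstack([u, u[-1:]])
    nq = cm.nq
    act = x[:, 2 * nq:] if p.excitation_driven else u_full
    forces = trajectory_forces(cm, x[:, :nq], x[:, nq:2 * nq], act)
    ok = bool(res.success and res.feas <= 1e-6)
    return EstimationResult(
        time=stream.time.copy(), states=x, controls=u_full, forces=forces,
        converged=np.full(len(stream), ok),
        iterations=np.full(len(stream), res.iterations),
        solve_seconds=np.full(len(stream), elapsed / len(stream)),
        config={"window": "full", "formulation": formulation,
                "variant": (weights or CostWeights()).variant,
                "dt": stream.dt})
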