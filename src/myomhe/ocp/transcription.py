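"""Direct multiple-shooting transcription of estimation / reference OCPs.

One :class:`MultipleShootingNLP` holds a window of ``n_nodes`` shooting
nodes spaced ``dt`` apart.  Decision variables are the states at every
node and the controls on every interval; interval continuity ("defect")
constraints ``x_{k+1} - Phi(x_k, u_k) = 0`` use the RK4 interval
integrator.  The cost is a weighted nonlinear least-squares sum of
optional per-node terms (marker tracking, EMG tracking, excitation
minimization, regularization, one-sided co-contraction floors), exposed
as residual vectors so the solver can build Gauss-Newton Hessians.

Defect Jacobians are computed by complex-step differentiation through
the integrator (machine precision, no step-size tuning), batched over
all intervals and perturbation directions at once.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ..model.dynamics import integrate_interval
from ..model.kinematics import CompiledModel

_CS_H = 1e-100  # complex-step size; derivatives are exact to O(h^2)
_CHUNK = 8192   # max batched dynamics evaluations per pass


class BufferingError(RuntimeError):
    """Window longer than the available measurements."""


class MultipleShootingNLP:
    """A window NLP over ``n_nodes`` states and ``n_nodes - 1`` controls."""

    def __init__(self, cm: CompiledModel, n_nodes: int, dt: float,
                 excitation_driven: bool = True, n_substeps: int = 1,
                 qd_bound: float = 20.0):
        if n_nodes < 2:
            raise ValueError("need at least 2 shooting nodes")
        self.cm = cm
        self.N = n_nodes
        self.dt = float(dt)
        self.excitation_driven = excitation_driven
        self.n_substeps = int(n_substeps)
        self.nq = cm.nq
        self.nu = cm.n_muscles
        self.nx = cm.state_size(excitation_driven)
        self.nvar = self.N * self.nx + (self.N - 1) * self.nu

        # default bounds: joint limits, symmetric velocity box, [0, 1]
        # activations and excitations
        na = self.nx - 2 * self.nq
        xlo = np.concatenate([cm.q_lower, -qd_bound * np.ones(self.nq),
                              np.zeros(na)])
        xhi = np.concatenate([cm.q_upper, qd_bound * np.ones(self.nq),
                              np.ones(na)])
        self.lb = np.concatenate([np.tile(xlo, self.N),
                                  np.zeros((self.N - 1) * self.nu)])
        self.ub = np.concatenate([np.tile(xhi, self.N),
                                  np.ones((self.N - 1) * self.nu)])

        # cost terms (all optional)
        self._marker_w = 0.0
        self._marker_targets = None  # (N, n_markers, 3), NaN = occluded
        self._emg_w = 0.0
        self._emg_targets = None     # (N-1, nu)
        self._u_pen_w = 0.0
        self._u_pen_target = 0.0
        self._q_track_w = 0.0
        self._q_track_targets = None
        self._qd_pen_w = 0.0
        self._a_pen_w = 0.0
        self._a_pen_target = 0.0
        self._cocon_w = 0.0
        self._cocon_idx = np.zeros(0, int)
        self._cocon_target = 0.0
        self._steady_w = 0.0
        self._layout = None

    # ------------------------------------------------------------ var layout
    def x_slice(self, k: int) -> slice:
        return slice(k * self.nx, (k + 1) * self.nx)

    def u_slice(self, k: int) -> slice:
        off = self.N * self.nx
        return slice(off + k * self.nu, off + (k + 1) * self.nu)

    def states(self, z: np.ndarray) -> np.ndarray:
        return z[: self.N * self.nx].reshape(self.N, self.nx)

    def controls(self, z: np.ndarray) -> np.ndarray:
        return z[self.N * self.nx:].reshape(self.N - 1, self.nu)

    def pack(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        return np.concatenate([np.asarray(x).ravel(), np.asarray(u).ravel()])

    # ---------------------------------------------------------------- bounds
    def fix_state(self, node: int, value: np.ndarray,
                  components: np.ndarray | slice | None = None) -> None:
        """Pin (a subset of) the state at ``node`` with an equality."""
        idx = np.arange(self.nx)[components if components is not None else
                                 slice(None)]
        base = node * self.nx
        self.lb[base + idx] = value
        self.ub[base + idx] = value

    def release_state(self, node: int) -> None:
        """Restore default bounds on the state at ``node``."""
        ref = self.N - 1 if node != self.N - 1 else self.N - 2
        self.lb[self.x_slice(node)] = self.lb[self.x_slice(ref)]
        self.ub[self.x_slice(node)] = self.ub[self.x_slice(ref)]

    # ------------------------------------------------------------ cost setup
    def set_marker_tracking(self, weight: float, targets: np.ndarray) -> None:
        targets = np.asarray(targets, float)
        if targets.shape != (self.N, self.cm.n_markers, 3):
            raise ValueError(f"marker targets must be "
                             f"{(self.N, self.cm.n_markers, 3)}, "
                             f"got {targets.shape}")
        self._marker_w = float(weight)
        self._marker_targets = targets
        self._layout = None

    def set_emg_tracking(self, weight: float, targets: np.ndarray) -> None:
        targets = np.asarray(targets, float)
        if targets.shape != (self.N - 1, self.nu):
            raise ValueError(f"EMG targets must be {(self.N - 1, self.nu)}, "
                             f"got {targets.shape}")
        self._emg_w = float(weight)
        self._emg_targets = targets
        self._layout = None

    def set_control_penalty(self, weight: float, target: float = 0.0) -> None:
        """Least-squared excitations (or activations) term.

        A nonzero ``target`` penalizes deviation from a constant resting
        level instead of zero.
        """
        self._u_pen_w = float(weight)
        self._u_pen_target = float(target)
        self._layout = None

    def set_q_tracking(self, weight: float, targets: np.ndarray) -> None:
        """Track a joint-angle trajectory (N, nq) directly."""
        targets = np.asarray(targets, float)
        if targets.shape != (self.N, self.nq):
            raise ValueError(f"q targets must be {(self.N, self.nq)}, "
                             f"got {targets.shape}")
        self._q_track_w = float(weight)
        self._q_track_targets = targets
        self._layout = None

    def set_velocity_penalty(self, weight: float) -> None:
        self._qd_pen_w = float(weight)
        self._layout = None

    def set_activation_penalty(self, weight: float, target: float = 0.0) -> None:
        if not self.excitation_driven and weight:
            raise ValueError("activation states exist only in the "
                             "excitation-driven formulation")
        self._a_pen_w = float(weight)
        self._a_pen_target = float(target)
        self._layout = None

    def set_steady_start_penalty(self, weight: float) -> None:
        """Penalize a_0 - u_0: the trajectory starts from the muscle
        steady state (excitation-driven formulation only)."""
        if not self.excitation_driven and weight:
            raise ValueError("steady-start coupling needs activation states")
        self._steady_w = float(weight)
        self._layout = None

    def set_cocontraction_floor(self, weight: float, muscle_idx,
                                target: float) -> None:
        """One-sided penalty max(0, target - u)^2 on selected controls."""
        self._cocon_w = float(weight)
        self._cocon_idx = np.asarray(muscle_idx, int)
        self._cocon_target = float(target)
        self._layout = None

    # ------------------------------------------------------- residual layout
    def _build_layout(self):
        rows = 0
        lay = {}
        if self._marker_w > 0:
            lay["markers"] = rows
            rows += self.N * self.cm.n_markers * 3
        if self._emg_w > 0:
            lay["emg"] = rows
            rows += (self.N - 1) * self.nu
        if self._q_track_w > 0:
            lay["q_track"] = rows
            rows += self.N * self.nq
        if self._u_pen_w > 0:
            lay["u_pen"] = rows
            rows += (self.N - 1) * self.nu
        if self._qd_pen_w > 0:
            lay["qd_pen"] = rows
            rows += self.N * self.nq
        if self._a_pen_w > 0:
            lay["a_pen"] = rows
            rows += self.N * (self.nx - 2 * self.nq)
        if self._cocon_w > 0:
            lay["cocon"] = rows
            rows += (self.N - 1) * len(self._cocon_idx)
        if self._steady_w > 0:
            lay["steady"] = rows
            rows += self.nu
        lay["n_rows"] = rows
        # static column index templates
        if self._marker_w > 0:
            nmk3 = self.cm.n_markers * 3
            node_rows = (lay["markers"]
                         + np.arange(self.N)[:, None, None] * nmk3
                         + np.arange(nmk3)[None, :, None])
            node_cols = (np.arange(self.N)[:, None, None] * self.nx
                         + np.arange(self.nq)[None, None, :])
            lay["mk_rows"] = np.broadcast_to(
                node_rows, (self.N, nmk3, self.nq)).ravel()
            lay["mk_cols"] = np.broadcast_to(
                node_cols, (self.N, nmk3, self.nq)).ravel()
        self._layout = lay
        return lay

    @property
    def layout(self):
        return self._layout or self._build_layout()

    # ------------------------------------------------------------- residuals
    def residuals(self, z: np.ndarray) -> np.ndarray:
        r, _ = self._residuals_impl(z, want_jac=False)
        return r

    def _residuals_impl(self, z, want_jac):
        lay = self.layout
        x = self.states(z)
        u = self.controls(z)
        q = x[:, : self.nq]
        r = np.zeros(lay["n_rows"])
        jac_rows, jac_cols, jac_data = [], [], []

        if self._marker_w > 0:
            sw = np.sqrt(self._marker_w)
            if want_jac:
                pos, jac = self.cm.marker_jacobians(q)
            else:
                pos = self.cm.marker_positions(q)
                jac = None
            res = sw * (pos - self._marker_targets)       # (N, M, 3)
            occluded = ~np.isfinite(self._marker_targets)
            res[occluded] = 0.0
            r[lay["markers"]:lay["markers"] + res.size] = res.ravel()
            if want_jac:
                jmk = sw * jac.reshape(self.N, -1, self.nq)
                jmk = jmk * (~occluded.reshape(self.N, -1))[..., None]
                jac_rows.append(lay["mk_rows"])
                jac_cols.append(lay["mk_cols"])
                jac_data.append(jmk.ravel())

        def linear_term(key, sw, vals, col_index):
            r[lay[key]:lay[key] + vals.size] = sw * vals.ravel()
            if want_jac:
                jac_rows.append(lay[key] + np.arange(vals.size))
                jac_cols.append(col_index)
                jac_data.append(np.full(vals.size, sw))

        off_u = self.N * self.nx
        u_cols = off_u + np.arange((self.N - 1) * self.nu)
        if self._emg_w > 0:
            linear_term("emg", np.sqrt(self._emg_w),
                        u - self._emg_targets, u_cols)
        if self._q_track_w > 0:
            q_cols = (np.arange(self.N)[:, None] * self.nx
                      + np.arange(self.nq)[None, :]).ravel()
            linear_term("q_track", np.sqrt(self._q_track_w),
                        q - self._q_track_targets, q_cols)
        if self._u_pen_w > 0:
            linear_term("u_pen", np.sqrt(self._u_pen_w),
                        u - self._u_pen_target, u_cols)
        if self._qd_pen_w > 0:
            qd_cols = (np.arange(self.N)[:, None] * self.nx
                       + self.nq + np.arange(self.nq)[None, :]).ravel()
            linear_term("qd_pen", np.sqrt(self._qd_pen_w),
                        x[:, self.nq:2 * self.nq], qd_cols)
        if self._a_pen_w > 0:
            na = self.nx - 2 * self.nq
            a_cols = (np.arange(self.N)[:, None] * self.nx
                      + 2 * self.nq + np.arange(na)[None, :]).ravel()
            linear_term("a_pen", np.sqrt(self._a_pen_w),
                        x[:, 2 * self.nq:] - self._a_pen_target, a_cols)
        if self._cocon_w > 0:
            # smoothed hinge: softplus(beta (t - u))/beta ~ max(0, t - u);
            # the smoothing keeps the Jacobian continuous at the floor,
            # which a Gauss-Newton iteration needs to avoid limit cycles
            beta = 200.0
            sw = np.sqrt(self._cocon_w)
            usel = u[:, self._cocon_idx]                  # (N-1, nsel)
            arg = beta * (self._cocon_target - usel)
            deficit = np.where(arg > 30, arg / beta,
                               np.log1p(np.exp(np.minimum(arg, 30.0))) / beta)
            r[lay["cocon"]:lay["cocon"] + deficit.size] = sw * deficit.ravel()
            if want_jac:
                sig = 1.0 / (1.0 + np.exp(np.clip(-arg, -500, 500)))
                cols = (off_u + np.arange(self.N - 1)[:, None] * self.nu
                        + self._cocon_idx[None, :]).ravel()
                jac_rows.append(lay["cocon"] + np.arange(deficit.size))
                jac_cols.append(cols)
                jac_data.append(-sw * sig.ravel())

        if self._steady_w > 0:
            sw = np.sqrt(self._steady_w)
            a0 = x[0, 2 * self.nq:]
            u0 = u[0]
            r[lay["steady"]:lay["steady"] + self.nu] = sw * (a0 - u0)
            if want_jac:
                rr = lay["steady"] + np.arange(self.nu)
                a_cols = 2 * self.nq + np.arange(self.nu)
                u_cols0 = off_u + np.arange(self.nu)
                jac_rows.append(np.concatenate([rr, rr]))
                jac_cols.append(np.concatenate([a_cols, u_cols0]))
                jac_data.append(np.concatenate([np.full(self.nu, sw),
                                                np.full(self.nu, -sw)]))

        J = None
        if want_jac:
            if jac_rows:
                J = sp.coo_matrix(
                    (np.concatenate(jac_data),
                     (np.concatenate(jac_rows), np.concatenate(jac_cols))),
                    shape=(lay["n_rows"], self.nvar)).tocsr()
            else:
                J = sp.csr_matrix((lay["n_rows"], self.nvar))
        return r, J

    # ------------------------------------------------------------- dynamics
    def _propagate(self, x, u):
        return integrate_interval(self.cm, x, u, self.dt, self.n_substeps,
                                  self.excitation_driven, check=False)

    def constraints(self, z: np.ndarray) -> np.ndarray:
        x = self.states(z)
        u = self.controls(z)
        phi = self._propagate(x[:-1], u)
        return (x[1:] - phi).ravel()

    def constraint_jacobian(self, z: np.ndarray
                            ) -> tuple[np.ndarray, sp.csr_matrix]:
        """Defects and their Jacobian, one complex-step batch."""
        x = self.states(z)
        u = self.controls(z)
        Nc = self.N - 1
        nd = self.nx + self.nu
        xe = np.repeat(x[:-1, None, :], nd, axis=1).astype(complex)
        ue = np.repeat(u[:, None, :], nd, axis=1).astype(complex)
        for d in range(self.nx):
            xe[:, d, d] += 1j * _CS_H
        for d in range(self.nu):
            ue[:, self.nx + d, d] += 1j * _CS_H
        xf = xe.reshape(Nc * nd, self.nx)
        uf = ue.reshape(Nc * nd, self.nu)
        out = np.empty_like(xf)
        for s in range(0, len(xf), _CHUNK):
            out[s:s + _CHUNK] = self._propagate(xf[s:s + _CHUNK],
                                                uf[s:s + _CHUNK])
        out = out.reshape(Nc, nd, self.nx)
        phi = np.real(out[:, 0, :])
        dphi = np.imag(out) / _CS_H                  # (Nc, nd, nx)
        c = (x[1:] - phi).ravel()

        # assemble sparse Jacobian: rows = defects, cols = variables
        blocks = -np.swapaxes(dphi, 1, 2)            # (Nc, nx, nd)
        rows = (np.arange(Nc)[:, None, None] * self.nx
                + np.arange(self.nx)[None, :, None])
        xcols = (np.arange(Nc)[:, None, None] * self.nx
                 + np.arange(self.nx)[None, None, :])
        ucols = (self.N * self.nx
                 + np.arange(Nc)[:, None, None] * self.nu
                 + np.arange(self.nu)[None, None, :])
        r_all = [np.broadcast_to(rows, (Nc, self.nx, self.nx)).ravel(),
                 np.broadcast_to(rows, (Nc, self.nx, self.nu)).ravel(),
                 np.arange(Nc * self.nx)]
        c_all = [np.broadcast_to(xcols, (Nc, self.nx, self.nx)).ravel(),
                 np.broadcast_to(ucols, (Nc, self.nx, self.nu)).ravel(),
                 (np.arange(Nc * self.nx) + self.nx)]
        d_all = [blocks[:, :, : self.nx].ravel(),
                 blocks[:, :, self.nx:].ravel(),
                 np.ones(Nc * self.nx)]
        # last block: +I on x_{k+1}; its flat column index is nx + row index
        J = sp.coo_matrix(
            (np.concatenate(d_all),
             (np.concatenate(r_all), np.concatenate(c_all))),
            shape=(Nc * self.nx, self.nvar)).tocsr()
        return c, J

    # ------------------------------------------------------- solver protocol
    def eval_vals(self, z):
        return self.residuals(z), self.constraints(z)

    def eval_all(self, z):
        r, Jr = self._residuals_impl(z, want_jac=True)
        c, Jc = self.constraint_jacobian(z)
        return r, Jr, c, Jc

    def eval_cost_jac(self, z):
        """Residuals with Jacobian plus constraint values only (lets the
        solver reuse a previously computed defect Jacobian)."""
        r, Jr = self._residuals_impl(z, want_jac=True)
        return r, Jr, self.constraints(z)

    def defect_norm(self, z: np.ndarray) -> float:
        """Max-norm continuity defect of a candidate solution."""
        return float(np.abs(self.constraints(z)).max())
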