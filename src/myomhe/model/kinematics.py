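"""Forward kinematics of the revolute chain, batched and complex-step safe.

All routines accept joint-angle arrays with arbitrary leading batch
dimensions and work transparently with complex dtype, which is how the
optimal-control layer obtains machine-precision derivatives of the
dynamics (complex-step differentiation).  Frames are indexed 0..nq with
frame 0 the fixed ground frame and frame j the frame moved by joint j
(1-based); ``CompiledModel`` caches this integer view of a
:class:`~myomhe.model.types.MusculoskeletalModel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import GROUND, MusculoskeletalModel


def cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product over the last axis; faster than np.cross and
    complex-safe (no broadcasting gymnastics)."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape),
                   dtype=np.result_type(a, b))
    a0, a1, a2 = a[..., 0], a[..., 1], a[..., 2]
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    out[..., 0] = a1 * b2 - a2 * b1
    out[..., 1] = a2 * b0 - a0 * b2
    out[..., 2] = a0 * b1 - a1 * b0
    return out


def _axis_rotation(axis: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Rodrigues rotation about a fixed unit ``axis`` (3,), batched angles."""
    c = np.cos(theta)[..., None, None]
    s = np.sin(theta)[..., None, None]
    a = axis
    eye = np.eye(3)
    outer = np.outer(a, a)
    skew = np.array([[0.0, -a[2], a[1]],
                     [a[2], 0.0, -a[0]],
                     [-a[1], a[0], 0.0]])
    return c * eye + (1.0 - c) * outer + s * skew


@dataclass(frozen=True)
class Frames:
    """World pose of every chain frame for a batch of configurations."""

    R: np.ndarray        # (..., nq+1, 3, 3) world orientation per frame
    origin: np.ndarray   # (..., nq+1, 3)   world origin per frame
    axis_w: np.ndarray   # (..., nq, 3)     world joint axes
    joint_origin: np.ndarray  # (..., nq, 3) world joint centres


class CompiledModel:
    """Numeric, array-based view of a model used by all math routines."""

    def __init__(self, model: MusculoskeletalModel):
        model.validate()
        self.model = model
        self.nq = model.nq
        joint_index = {GROUND: 0}
        for i, j in enumerate(model.joints):
            joint_index[j.name] = i + 1
        self.parent = np.array([joint_index[j.parent] for j in model.joints])
        self.joint_origin_local = np.array([j.origin for j in model.joints], float)
        axes = np.array([j.axis for j in model.joints], float)
        self.axis_local = axes / np.linalg.norm(axes, axis=1, keepdims=True)
        self.q_lower = np.array([j.limits[0] for j in model.joints])
        self.q_upper = np.array([j.limits[1] for j in model.joints])
        self.gravity = np.asarray(model.gravity, float)

        seg_frame = {s.name: joint_index[s.frame] for s in model.segments}
        # ancestry: anc[j, f] == joint j (0-based) moves frame f (0..nq)
        anc = np.zeros((self.nq, self.nq + 1), dtype=bool)
        for f in range(1, self.nq + 1):
            g = f
            while g != 0:
                anc[g - 1, f] = True
                g = self.parent[g - 1]
        self.ancestor = anc

        # rigid bodies (segments with mass)
        bodies = [s for s in model.segments if s.mass > 0]
        self.body_frame = np.array([seg_frame[s.name] for s in bodies], int)
        self.body_mass = np.array([s.mass for s in bodies], float)
        self.body_com = np.array([s.com for s in bodies], float)
        self.body_inertia = np.array([np.diag(s.inertia) for s in bodies], float)

        # markers
        self.marker_frame = np.array([seg_frame[m.segment] for m in model.markers], int)
        self.marker_local = np.array([m.position for m in model.markers], float)

        # muscle path points, flattened; edges connect consecutive points
        pf, pl, e_a, e_b, e_mus = [], [], [], [], []
        for im, mus in enumerate(model.muscles):
            start = len(pf)
            for p in mus.path:
                pf.append(seg_frame[p.segment])
                pl.append(p.position)
            for k in range(len(mus.path) - 1):
                e_a.append(start + k)
                e_b.append(start + k + 1)
                e_mus.append(im)
        self.point_frame = np.array(pf, int)
        self.point_local = np.array(pl, float).reshape(len(pf), 3)
        self.edge_a = np.array(e_a, int)
        self.edge_b = np.array(e_b, int)
        self.edge_muscle = np.array(e_mus, int)
        self.n_muscles = model.n_muscles
        # per-muscle sum over path edges as a dense (M, E) matrix
        self.muscle_edge_sum = np.zeros((self.n_muscles, len(e_a)))
        self.muscle_edge_sum[self.edge_muscle, np.arange(len(e_a))] = 1.0
        # muscle parameter arrays
        self.f_iso_max = np.array([m.f_iso_max for m in model.muscles])
        self.l_opt = np.array([m.l_opt for m in model.muscles])
        self.l_ts = np.array([m.l_ts for m in model.muscles])
        self.v_max = np.array([m.v_max for m in model.muscles])
        self.tau_act = np.array([m.tau_act for m in model.muscles])
        self.tau_deact = np.array([m.tau_deact for m in model.muscles])
        self.delay = np.array([m.delay for m in model.muscles])

    # ------------------------------------------------------------------ sizes
    @property
    def n_markers(self) -> int:
        return len(self.marker_frame)

    def state_size(self, excitation_driven: bool) -> int:
        return 2 * self.nq + (self.n_muscles if excitation_driven else 0)

    # ------------------------------------------------------------------- FK
    def frames(self, q: np.ndarray) -> Frames:
        """Compute world poses of all frames for angles ``q`` (..., nq)."""
        q = np.asarray(q)
        batch = q.shape[:-1]
        dtype = q.dtype if np.iscomplexobj(q) else float
        R = np.zeros(batch + (self.nq + 1, 3, 3), dtype=dtype)
        o = np.zeros(batch + (self.nq + 1, 3), dtype=dtype)
        aw = np.zeros(batch + (self.nq, 3), dtype=dtype)
        jo = np.zeros(batch + (self.nq, 3), dtype=dtype)
        R[..., 0, :, :] = np.eye(3)
        for j in range(self.nq):
            p = self.parent[j]
            Rp = R[..., p, :, :]
            op = o[..., p, :]
            centre = op + (Rp @ self.joint_origin_local[j])
            a_w = Rp @ self.axis_local[j]
            Rj = Rp @ _axis_rotation(self.axis_local[j], q[..., j])
            R[..., j + 1, :, :] = Rj
            o[..., j + 1, :] = centre
            aw[..., j, :] = a_w
            jo[..., j, :] = centre
        return Frames(R=R, origin=o, axis_w=aw, joint_origin=jo)

    def points_world(self, fr: Frames, frame_idx: np.ndarray,
                     local: np.ndarray) -> np.ndarray:
        """Map local points (P, 3) on frames (P,) to world, batched."""
        Rf = fr.R[..., frame_idx, :, :]          # (..., P, 3, 3)
        of = fr.origin[..., frame_idx, :]        # (..., P, 3)
        return of + np.einsum("...pij,pj->...pi", Rf, local)

    def point_jacobians(self, fr: Frames, frame_idx: np.ndarray,
                        p_world: np.ndarray) -> np.ndarray:
        """Geometric Jacobians d p_world / d q, shape (..., P, 3, nq).

        Column j is a_j x (p - o_j) when joint j is an ancestor of the
        point's frame, zero otherwise.
        """
        rel = p_world[..., :, None, :] - fr.joint_origin[..., None, :, :]
        cols = cross3(fr.axis_w[..., None, :, :], rel)    # (..., P, nq, 3)
        mask = self.ancestor[:, frame_idx].T              # (P, nq)
        cols = cols * mask[..., :, :, None]
        return np.swapaxes(cols, -1, -2)                  # (..., P, 3, nq)

    def marker_positions(self, q: np.ndarray) -> np.ndarray:
        """World marker positions (..., n_markers, 3)."""
        fr = self.frames(q)
        return self.points_world(fr, self.marker_frame, self.marker_local)

    def marker_jacobians(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Marker positions and their Jacobians wrt q."""
        fr = self.frames(q)
        pw = self.points_world(fr, self.marker_frame, self.marker_local)
        return pw, self.point_jacobians(fr, self.marker_frame, pw)


def forward_kinematics(model: MusculoskeletalModel | CompiledModel,
                       q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Marker positions (..., n_markers, 3) and frame poses for angles ``q``.

    Returns ``(markers, frames_hom)`` where ``frames_hom`` stacks 4x4
    homogeneous transforms of every chain frame, shape (..., nq+1, 4, 4).
    """
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    q = np.asarray(q, dtype=float)
    fr = cm.frames(q)
    markers = cm.points_world(fr, cm.marker_frame, cm.marker_local)
    hom = np.zeros(q.shape[:-1] + (cm.nq + 1, 4, 4))
    hom[..., :3, :3] = fr.R
    hom[..., :3, 3] = fr.origin
    hom[..., 3, 3] = 1.0
    return markers, hom
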