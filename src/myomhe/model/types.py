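"""Domain types for musculoskeletal arm models.

A model is a serial chain of revolute joints rooted in a fixed ground
("thorax") frame.  Body segments, skin markers and muscle path points all
attach to a frame of that chain; muscles are polyline lines of action
(origin, optional via points, insertion) driving Hill-type force elements.

The on-disk representation is a small YAML document with sections
``joints`` / ``segments`` / ``markers`` / ``muscles``; see
:func:`MusculoskeletalModel.from_yaml` and the packaged ``arm4d19.yaml``
for a complete example.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

GROUND = "ground"


class ModelValidationError(ValueError):
    """Raised when a model description violates a structural invariant."""


@dataclass
class Joint:
    """A revolute degree of freedom.

    ``origin`` is the joint centre expressed in the parent frame, ``axis``
    the (unit) rotation axis in the joint's own pre-rotation frame and
    ``limits`` the admissible angle range in radians.
    """

    name: str
    parent: str  # GROUND or the name of another joint
    origin: tuple[float, float, float]
    axis: tuple[float, float, float]
    limits: tuple[float, float]


@dataclass
class Segment:
    """A rigid body attached to a joint frame (or to ground)."""

    name: str
    frame: str  # joint name or GROUND
    mass: float = 0.0
    com: tuple[float, float, float] = (0.0, 0.0, 0.0)
    inertia: tuple[float, float, float] = (0.0, 0.0, 0.0)  # principal, kg m^2


@dataclass
class Marker:
    name: str
    segment: str
    position: tuple[float, float, float]  # local, m


@dataclass
class PathPoint:
    segment: str
    position: tuple[float, float, float]  # local, m


@dataclass
class MuscleElement:
    """One Hill-type line of action.

    Force parameters: maximum isometric force ``f_iso_max`` (N), optimal
    fiber length ``l_opt`` (m), tendon slack length ``l_ts`` (m, rigid
    tendon), maximum shortening velocity ``v_max`` (optimal fiber lengths
    per second), activation/deactivation time constants (s), and the
    electromechanical delay between excitation and activation (s).
    """

    name: str
    path: list[PathPoint]
    f_iso_max: float
    l_opt: float
    l_ts: float
    v_max: float = 10.0
    tau_act: float = 0.015
    tau_deact: float = 0.060
    delay: float = 0.020

    def validate(self) -> None:
        if len(self.path) < 2:
            raise ModelValidationError(
                f"muscle {self.name!r}: path needs >= 2 points (origin, insertion)")
        if not self.f_iso_max > 0:
            raise ModelValidationError(f"muscle {self.name!r}: f_iso_max must be > 0")
        if not self.l_opt > 0:
            raise ModelValidationError(f"muscle {self.name!r}: l_opt must be > 0")
        if not self.v_max > 0:
            raise ModelValidationError(f"muscle {self.name!r}: v_max must be > 0")
        if not 0 < self.tau_act <= self.tau_deact:
            raise ModelValidationError(
                f"muscle {self.name!r}: need 0 < tau_act <= tau_deact")


@dataclass
class MusculoskeletalModel:
    """Complete arm model: the single source of truth for all dynamics."""

    name: str
    joints: list[Joint]
    segments: list[Segment]
    markers: list[Marker]
    muscles: list[MuscleElement]
    gravity: tuple[float, float, float] = (0.0, 0.0, -9.81)

    # ------------------------------------------------------------------ sizes
    @property
    def nq(self) -> int:
        return len(self.joints)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    @property
    def joint_limits(self) -> np.ndarray:
        """(nq, 2) array of [lower, upper] joint angles in radians."""
        return np.array([j.limits for j in self.joints], dtype=float)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        """Check structural invariants; raise :class:`ModelValidationError`."""
        joint_names = [j.name for j in self.joints]
        if len(set(joint_names)) != len(joint_names):
            raise ModelValidationError("duplicate joint names")
        known_frames = {GROUND}
        for j in self.joints:
            if j.parent not in known_frames:
                raise ModelValidationError(
                    f"joint {j.name!r}: parent {j.parent!r} undeclared (joints must "
                    "be listed parent-first)")
            ax = np.asarray(j.axis, dtype=float)
            if not np.isfinite(ax).all() or np.linalg.norm(ax) < 1e-12:
                raise ModelValidationError(f"joint {j.name!r}: invalid axis")
            if not j.limits[0] < j.limits[1]:
                raise ModelValidationError(f"joint {j.name!r}: empty limit range")
            known_frames.add(j.name)
        seg_names = set()
        for s in self.segments:
            if s.frame not in known_frames:
                raise ModelValidationError(
                    f"segment {s.name!r}: unknown frame {s.frame!r}")
            if s.mass < 0:
                raise ModelValidationError(f"segment {s.name!r}: negative mass")
            seg_names.add(s.name)
        for m in self.markers:
            if m.segment not in seg_names:
                raise ModelValidationError(
                    f"marker {m.name!r}: unknown segment reference {m.segment!r}")
        for mus in self.muscles:
            mus.validate()
            for p in mus.path:
                if p.segment not in seg_names:
                    raise ModelValidationError(
                        f"muscle {mus.name!r}: path point on unknown segment "
                        f"{p.segment!r}")

    def segment_frame(self, segment_name: str) -> str:
        for s in self.segments:
            if s.name == segment_name:
                return s.frame
        raise ModelValidationError(f"unknown segment {segment_name!r}")

    # ------------------------------------------------------------------- yaml
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "gravity": [float(g) for g in self.gravity],
            "joints": [
                {"name": j.name, "parent": j.parent,
                 "origin": [float(v) for v in j.origin],
                 "axis": [float(v) for v in j.axis],
                 "limits": [float(v) for v in j.limits]}
                for j in self.joints
            ],
            "segments": [
                {"name": s.name, "frame": s.frame, "mass": float(s.mass),
                 "com": [float(v) for v in s.com],
                 "inertia": [float(v) for v in s.inertia]}
                for s in self.segments
            ],
            "markers": [
                {"name": m.name, "segment": m.segment,
                 "position": [float(v) for v in m.position]}
                for m in self.markers
            ],
            "muscles": [
                {"name": m.name, "f_iso_max": float(m.f_iso_max),
                 "l_opt": float(m.l_opt), "l_ts": float(m.l_ts),
                 "v_max": float(m.v_max), "tau_act": float(m.tau_act),
                 "tau_deact": float(m.tau_deact), "delay": float(m.delay),
                 "path": [{"segment": p.segment,
                           "position": [float(v) for v in p.position]}
                          for p in m.path]}
                for m in self.muscles
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MusculoskeletalModel":
        model = cls(
            name=d["name"],
            gravity=tuple(d.get("gravity", (0.0, 0.0, -9.81))),
            joints=[Joint(name=j["name"], parent=j["parent"],
                          origin=tuple(j["origin"]), axis=tuple(j["axis"]),
                          limits=tuple(j["limits"])) for j in d["joints"]],
            segments=[Segment(name=s["name"], frame=s["frame"],
                              mass=s.get("mass", 0.0),
                              com=tuple(s.get("com", (0, 0, 0))),
                              inertia=tuple(s.get("inertia", (0, 0, 0))))
                      for s in d["segments"]],
            markers=[Marker(name=m["name"], segment=m["segment"],
                            position=tuple(m["position"])) for m in d["markers"]],
            muscles=[MuscleElement(
                name=m["name"], f_iso_max=m["f_iso_max"], l_opt=m["l_opt"],
                l_ts=m["l_ts"], v_max=m.get("v_max", 10.0),
                tau_act=m.get("tau_act", 0.015),
                tau_deact=m.get("tau_deact", 0.060),
                delay=m.get("delay", 0.020),
                path=[PathPoint(segment=p["segment"], position=tuple(p["position"]))
                      for p in m["path"]]) for m in d["muscles"]],
        )
        model.validate()
        return model

    def to_yaml(self, path: str | Path) -> None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(text)
        tmp.replace(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MusculoskeletalModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the model parameters, recorded in run sidecars."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]
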