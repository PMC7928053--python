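"""Construction of the shipped models.

``arm_model()`` returns the flagship 4-DoF / 19-muscle / 8-marker arm:
a fixed thorax, a humerus with three glenohumeral rotations (plane of
elevation, elevation, axial rotation) and a forearm with elbow flexion.
Muscle strengths follow the Holzbaur upper-limb dataset; attachment
coordinates are plausible hand-placed values (documented placeholders)
and optimal-fiber / tendon-slack lengths are calibrated once, from the
geometry itself, so every element operates near its optimal length over
the task workspace.  The resolved numbers are frozen in the packaged
``arm4d19.yaml`` config, which is the loaded source of truth.

``planar_fixture_model()`` is a 2-DoF, 6-muscle, 4-marker sagittal arm
with the same schema, small enough that a full reference optimal-control
solve runs in seconds; the test-suite workhorse.
"""

from __future__ import annotations

import importlib.resources
from itertools import product

import numpy as np

from .kinematics import CompiledModel
from .muscle import musculotendon_geometry
from .types import (GROUND, Joint, Marker, MusculoskeletalModel,
                    MuscleElement, PathPoint, Segment)

#: muscle elements forming the agonist/antagonist pair used by the
#: co-contraction task term (triceps + biceps heads of the arm model)
ARM_COCONTRACTION_PAIR = ("tri_long", "tri_lat", "tri_med",
                          "bic_long", "bic_short")

#: joint-space box spanned by the default cyclic task; also the region
#: over which fiber/tendon lengths are calibrated.  The excursions are
#: sized so a 2 s cycle reproduces the joint-velocity regime of a slow
#: cyclic arm movement (a full-amplitude cycle would need ~8 s)
ARM_TASK_BOX = ((0.05, 0.3), (-0.65, -0.3), (0.05, 0.25), (0.5, 1.2))

FIXTURE_COCONTRACTION_PAIR = ("el_flex", "bi_flex", "el_ext", "bi_ext")
FIXTURE_TASK_BOX = ((0.1, 0.8), (0.4, 1.1))


def calibrate_fiber_parameters(model: MusculoskeletalModel,
                               task_box, n_grid: int = 5) -> None:
    """Set l_opt / l_ts per muscle from the musculotendon length range.

    Samples a deterministic joint grid over ``task_box``, then chooses
    l_opt = max(4 * half-range, 0.05 m) so the normalized fiber length
    stays within about [0.75, 1.25] over the workspace (keeping passive
    stretch forces moderate), and l_ts so the mid-range fiber length is
    optimal.  Mutates ``model`` in place.
    """
    cm = CompiledModel(model)
    axes = [np.linspace(lo, hi, n_grid) for lo, hi in task_box]
    grid = np.array(list(product(*axes)))
    l_mt, _, _ = musculotendon_geometry(cm, grid)
    l_min, l_max = l_mt.min(axis=0), l_mt.max(axis=0)
    l_mid = 0.5 * (l_min + l_max)
    half = 0.5 * (l_max - l_min)
    for i, mus in enumerate(model.muscles):
        l_opt = max(4.0 * half[i], 0.05)
        l_ts = max(l_mid[i] - l_opt, 0.005)
        mus.l_opt = float(min(l_opt, l_mid[i] - 0.005))
        mus.l_ts = float(l_ts)


# --------------------------------------------------------------------- arm
_ARM_F_ISO = {
    "pec_clav": 364.4, "pec_ster": 515.4, "pec_rib": 390.5,
    "lat_thor": 389.1, "lat_lumb": 287.3, "lat_ilio": 204.7,
    "delt_ant": 1142.6, "delt_mid": 1142.6, "delt_post": 259.9,
    "supra": 487.8, "infra": 1210.8, "subsc": 1377.8,
    "tri_long": 798.5, "tri_lat": 624.3, "tri_med": 624.3,
    "brachiorad": 261.3, "brachialis": 987.3,
    "bic_long": 624.3, "bic_short": 435.6,
}

# thorax (T) points in ground frame, humerus (H) local to gh_rot frame,
# ulna (U) / radius (R) local to the elbow frame
_ARM_PATHS = {
    "pec_clav": [("thorax", (0.05, -0.10, 0.01)), ("humerus", (0.015, 0.005, -0.06))],
    "pec_ster": [("thorax", (0.06, -0.12, -0.03)), ("humerus", (0.015, 0.005, -0.07))],
    "pec_rib": [("thorax", (0.05, -0.12, -0.09)), ("humerus", (0.012, 0.005, -0.075))],
    "lat_thor": [("thorax", (-0.07, -0.10, -0.08)), ("humerus", (0.008, -0.005, -0.09))],
    "lat_lumb": [("thorax", (-0.07, -0.11, -0.14)), ("humerus", (0.008, -0.005, -0.10))],
    "lat_ilio": [("thorax", (-0.06, -0.11, -0.20)), ("humerus", (0.008, -0.005, -0.11))],
    "delt_ant": [("thorax", (0.035, -0.03, 0.015)), ("humerus", (0.012, 0.022, -0.11))],
    # the middle deltoid arcs over the humeral head; the lateral via
    # point gives it its abduction moment arm at the hanging posture
    "delt_mid": [("thorax", (0.0, 0.005, 0.035)), ("thorax", (0.0, 0.045, 0.015)),
                 ("humerus", (0.002, 0.028, -0.11))],
    "delt_post": [("thorax", (-0.04, -0.03, 0.015)), ("humerus", (-0.012, 0.022, -0.11))],
    "supra": [("thorax", (-0.045, -0.045, 0.01)), ("thorax", (-0.005, 0.0, 0.035)),
              ("humerus", (0.0, 0.022, -0.015))],
    "infra": [("thorax", (-0.065, -0.04, -0.01)), ("humerus", (-0.018, 0.016, -0.02))],
    "subsc": [("thorax", (-0.05, -0.05, -0.015)), ("humerus", (0.018, 0.012, -0.02))],
    "tri_long": [("thorax", (-0.045, -0.02, -0.005)), ("humerus", (-0.02, 0.0, -0.28)),
                 ("ulna", (-0.025, 0.0, 0.012))],
    "tri_lat": [("humerus", (-0.01, 0.008, -0.10)), ("humerus", (-0.02, 0.0, -0.28)),
                ("ulna", (-0.025, 0.0, 0.012))],
    "tri_med": [("humerus", (-0.01, -0.008, -0.14)), ("humerus", (-0.02, 0.0, -0.28)),
                ("ulna", (-0.025, 0.0, 0.012))],
    "brachiorad": [("humerus", (0.008, 0.02, -0.23)), ("radius", (0.015, 0.01, -0.18))],
    "brachialis": [("humerus", (0.012, 0.0, -0.16)), ("ulna", (0.018, 0.0, -0.03))],
    "bic_long": [("thorax", (0.012, 0.01, 0.02)), ("humerus", (0.022, 0.005, -0.05)),
                 ("humerus", (0.022, 0.0, -0.27)), ("radius", (0.015, 0.0, -0.045))],
    "bic_short": [("thorax", (0.035, -0.015, 0.005)), ("humerus", (0.02, -0.005, -0.27)),
                  ("radius", (0.015, 0.0, -0.045))],
}

_ARM_MARKERS = [
    ("m_delt", "humerus", (0.0, 0.035, -0.12)),
    ("m_shaft", "humerus", (0.005, 0.03, -0.20)),
    ("m_cond_med", "humerus", (0.0, -0.035, -0.285)),
    ("m_cond_lat", "humerus", (0.0, 0.035, -0.285)),
    ("m_olecranon", "ulna", (-0.035, 0.0, 0.01)),
    ("m_ulna_lat", "ulna", (0.0, 0.028, -0.15)),
    ("m_uln_styloid", "ulna", (0.0, -0.02, -0.235)),
    ("m_rad_styloid", "radius", (0.02, 0.02, -0.235)),
]


def generate_arm_model() -> MusculoskeletalModel:
    """Build the 4-DoF / 19-muscle arm from scratch (used to produce the
    packaged config; prefer :func:`arm_model` for everyday use)."""
    joints = [
        Joint("gh_plane", GROUND, (0.0, 0.0, 0.0), (0.0, 0.0, 1.0),
              (-np.pi / 2, np.pi / 2)),
        Joint("gh_elev", "gh_plane", (0.0, 0.0, 0.0), (1.0, 0.0, 0.0),
              (-2.0, np.pi / 2)),
        Joint("gh_rot", "gh_elev", (0.0, 0.0, 0.0), (0.0, 0.0, 1.0),
              (-np.pi / 2, np.pi / 2)),
        Joint("elbow_flex", "gh_rot", (0.0, 0.0, -0.30), (0.0, -1.0, 0.0),
              (-0.5, 2.1)),
    ]
    segments = [
        Segment("thorax", GROUND),
        Segment("humerus", "gh_rot", mass=2.05, com=(0.0, 0.0, -0.13),
                inertia=(0.014, 0.014, 0.0025)),
        Segment("ulna", "elbow_flex", mass=1.25, com=(0.0, 0.0, -0.11),
                inertia=(0.0075, 0.0075, 0.0011)),
        Segment("radius", "elbow_flex", mass=0.35, com=(0.01, 0.0, -0.15),
                inertia=(0.0030, 0.0030, 0.0004)),
    ]
    markers = [Marker(n, s, p) for n, s, p in _ARM_MARKERS]
    muscles = [
        MuscleElement(name=name,
                      path=[PathPoint(seg, pos) for seg, pos in _ARM_PATHS[name]],
                      f_iso_max=_ARM_F_ISO[name], l_opt=0.1, l_ts=0.1)
        for name in _ARM_F_ISO
    ]
    model = MusculoskeletalModel(name="arm4d19", joints=joints,
                                 segments=segments, markers=markers,
                                 muscles=muscles)
    calibrate_fiber_parameters(model, ARM_TASK_BOX)
    model.validate()
    return model


def arm_model() -> MusculoskeletalModel:
    """Load the packaged 4-DoF / 19-muscle arm configuration."""
    ref = importlib.resources.files("myomhe.data") / "arm4d19.yaml"
    with importlib.resources.as_file(ref) as path:
        return MusculoskeletalModel.from_yaml(path)


# ----------------------------------------------------------------- fixture
def planar_fixture_model() -> MusculoskeletalModel:
    """2-DoF, 6-muscle, 4-marker sagittal-plane arm for fast tests."""
    joints = [
        Joint("shoulder", GROUND, (0.0, 0.0, 0.0), (0.0, -1.0, 0.0),
              (-1.0, 2.5)),
        Joint("elbow", "shoulder", (0.0, 0.0, -0.28), (0.0, -1.0, 0.0),
              (-0.5, 2.1)),
    ]
    segments = [
        Segment("base", GROUND),
        Segment("upperarm", "shoulder", mass=1.8, com=(0.0, 0.0, -0.13),
                inertia=(0.012, 0.012, 0.002)),
        Segment("forearm", "elbow", mass=1.1, com=(0.0, 0.0, -0.11),
                inertia=(0.008, 0.008, 0.001)),
    ]
    markers = [
        Marker("ua1", "upperarm", (0.02, 0.0, -0.10)),
        Marker("ua2", "upperarm", (0.02, 0.0, -0.22)),
        Marker("fa1", "forearm", (0.02, 0.0, -0.08)),
        Marker("fa2", "forearm", (0.02, 0.0, -0.20)),
    ]
    paths = {
        "sh_flex": [("base", (0.05, 0.0, 0.02)), ("upperarm", (0.02, 0.0, -0.12))],
        "sh_ext": [("base", (-0.05, 0.0, 0.02)), ("upperarm", (-0.02, 0.0, -0.12))],
        "el_flex": [("upperarm", (0.015, 0.0, -0.15)),
                    ("upperarm", (0.025, 0.0, -0.255)),
                    ("forearm", (0.02, 0.0, -0.04))],
        "el_ext": [("upperarm", (-0.015, 0.0, -0.12)),
                   ("upperarm", (-0.025, 0.0, -0.255)),
                   ("forearm", (-0.03, 0.0, 0.01))],
        "bi_flex": [("base", (0.04, 0.0, 0.0)),
                    ("upperarm", (0.025, 0.0, -0.245)),
                    ("forearm", (0.02, 0.0, -0.05))],
        "bi_ext": [("base", (-0.04, 0.0, 0.0)),
                   ("upperarm", (-0.025, 0.0, -0.25)),
                   ("forearm", (-0.03, 0.0, 0.012))],
    }
    f_iso = {"sh_flex": 600.0, "sh_ext": 600.0, "el_flex": 500.0,
             "el_ext": 600.0, "bi_flex": 400.0, "bi_ext": 350.0}
    muscles = [
        MuscleElement(name=n, path=[PathPoint(s, p) for s, p in pts],
                      f_iso_max=f_iso[n], l_opt=0.1, l_ts=0.1)
        for n, pts in paths.items()
    ]
    model = MusculoskeletalModel(name="planar_arm", joints=joints,
                                 segments=segments, markers=markers,
                                 muscles=muscles,
                                 gravity=(0.0, 0.0, -9.81))
    calibrate_fiber_parameters(model, FIXTURE_TASK_BOX, n_grid=9)
    model.validate()
    return model
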