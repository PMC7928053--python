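"""Shared fixtures: models and (expensive, session-scoped) reference data."""

from __future__ import annotations

import numpy as np
import pytest

from myomhe.model import CompiledModel, arm_model, planar_fixture_model

#: desk-scale reference configuration used throughout the fixture tests
FIXTURE_DURATION = 2.0
FIXTURE_NODES = 100


@pytest.fixture(scope="session")
def fixture_model():
    return planar_fixture_model()


@pytest.fixture(scope="session")
def fixture_cm(fixture_model):
    return CompiledModel(fixture_model)


@pytest.fixture(scope="session")
def arm():
    return arm_model()


@pytest.fixture(scope="session")
def arm_cm(arm):
    return CompiledModel(arm)


@pytest.fixture(scope="session")
def fixture_reference(fixture_model):
    """Plain (no co-contraction) fixture reference dataset."""
    from myomhe.reference import solve_reference

    ds, res = solve_reference(fixture_model, duration_s=FIXTURE_DURATION,
                              n_nodes=FIXTURE_NODES,
                              cocontraction_level="none")
    assert res.feas <= 1e-8
    return ds


@pytest.fixture(scope="session")
def fixture_reference_family(fixture_model):
    """All four co-contraction levels of the fixture task."""
    from myomhe.reference import solve_reference_family

    fam = solve_reference_family(fixture_model,
                                 levels=("none", "low", "mid", "high"),
                                 duration_s=FIXTURE_DURATION,
                                 n_nodes=FIXTURE_NODES)
    return {lvl: ds for lvl, (ds, _res) in fam.items()}


@pytest.fixture(scope="session")
def fixture_noiseless_mhe(fixture_cm, fixture_reference):
    """Window-7 excitation-driven MHE run on noiseless fixture data."""
    from myomhe.mhe import MeasurementStream, MheProblem, run_mhe

    stream = MeasurementStream.from_reference(fixture_reference)
    result = run_mhe(fixture_cm, stream, MheProblem(window=7))
    return result


def random_configurations(cm, n, seed=0, margin=0.1):
    """Joint angles drawn uniformly inside the (shrunk) limit box."""
    rng = np.random.default_rng(seed)
    span = cm.q_upper - cm.q_lower
    lo = cm.q_lower + margin * span
    hi = cm.q_upper - margin * span
    return lo + (hi - lo) * rng.random((n, cm.nq))
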