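"""Reference-motion generator: dynamic consistency, cyclicity,
co-contraction levels, dataset round-trips."""

from __future__ import annotations

import numpy as np
import pytest

from myomhe.model import CompiledModel, hill_force, musculotendon_geometry
from myomhe.ocp import MultipleShootingNLP
from myomhe.reference import (COCONTRACTION_TARGETS, ReferenceWeights,
                              build_reference_ocp, extract_muscle_forces,
                              cocontraction_indices)

from conftest import FIXTURE_DURATION, FIXTURE_NODES


def test_reference_is_dynamically_consistent(fixture_cm, fixture_reference):
    """Max continuity defect of the returned dataset below 1e-8."""
    ds = fixture_reference
    nlp = MultipleShootingNLP(fixture_cm, ds.n_frames, ds.dt)
    x = np.concatenate([ds.q, ds.qdot, ds.activations], axis=1)
    z = nlp.pack(x, ds.excitations[:-1])
    assert nlp.defect_norm(z) < 1e-8


def test_reference_is_cyclic(fixture_reference):
    ds = fixture_reference
    assert np.abs(ds.q[0] - ds.q[-1]).max() < 1e-6
    assert np.abs(ds.qdot[0] - ds.qdot[-1]).max() < 1e-6
    assert np.abs(ds.qdot[0]).max() < 1e-6     # starts at rest


def test_reference_markers_equal_forward_kinematics(fixture_cm,
                                                    fixture_reference):
    ds = fixture_reference
    np.testing.assert_array_equal(ds.markers,
                                  fixture_cm.marker_positions(ds.q))


def test_excitations_within_bounds(fixture_reference):
    ds = fixture_reference
    assert ds.excitations.min() >= 0.0
    assert ds.excitations.max() <= 1.0


def test_cocontraction_monotone_and_kinematics_invariant(
        fixture_model, fixture_reference_family):
    """Mean antagonist-pair excitation is non-decreasing across levels
    and joint trajectories stay within 1 deg RMSE of the plain level."""
    fam = fixture_reference_family
    idx = cocontraction_indices(fixture_model)
    means = {lvl: fam[lvl].excitations[:, idx].mean()
             for lvl in ("none", "low", "mid", "high")}
    assert means["none"] <= means["low"] <= means["mid"] <= means["high"]
    # floors are effective: pair mean approaches each level's target
    for lvl in ("low", "mid", "high"):
        assert means[lvl] > 0.9 * COCONTRACTION_TARGETS[lvl]
        q_rmse = np.degrees(np.sqrt(
            ((fam[lvl].q - fam["none"].q) ** 2).mean()))
        assert q_rmse < 1.0


def test_extract_muscle_forces_matches_independent_evaluation(
        fixture_cm, fixture_reference):
    """Spot-check: dataset forces equal a hand-chained geometry->Hill
    evaluation outside the NLP machinery, and are deterministic."""
    ds = fixture_reference
    f1 = extract_muscle_forces(fixture_cm, ds)
    f2 = extract_muscle_forces(fixture_cm, ds)
    np.testing.assert_array_equal(f1, f2)
    k = ds.n_frames // 3
    l_mt, _, v_mt = musculotendon_geometry(fixture_cm, ds.q[k], ds.qdot[k])
    expected = hill_force(fixture_cm, ds.activations[k], l_mt, v_mt)
    np.testing.assert_allclose(f1[k], expected, rtol=1e-12)
    np.testing.assert_allclose(ds.forces[k], expected, rtol=1e-12)
    assert f1.min() >= 0.0


def test_zero_cocontraction_weight_reproduces_plain_problem(fixture_cm):
    """Level none and a zero-weight floor build identical costs."""
    w = ReferenceWeights(cocontraction=0.0)
    nlp_a, z_a = build_reference_ocp(fixture_cm, FIXTURE_DURATION,
                                     FIXTURE_NODES, "none")
    nlp_b, _ = build_reference_ocp(fixture_cm, FIXTURE_DURATION,
                                   FIXTURE_NODES, "mid", weights=w)
    ra = nlp_a.residuals(z_a)
    rb = nlp_b.residuals(z_a)
    np.testing.assert_array_equal(ra, rb)


def test_node_grid_arithmetic(fixture_cm):
    """800 intervals over 8 s means a 100 Hz grid (dt = 10 ms)."""
    nlp, _ = build_reference_ocp(fixture_cm, 8.0, 800, "none")
    assert nlp.N == 801
    assert nlp.dt == pytest.approx(0.01)


def test_invalid_level_rejected(fixture_cm):
    with pytest.raises(ValueError):
        build_reference_ocp(fixture_cm, 2.0, 100, "extreme")


def test_dataset_roundtrip(tmp_path, fixture_model, fixture_reference):
    from myomhe.io import read_reference_dataset, write_reference_dataset

    write_reference_dataset(fixture_reference, tmp_path,
                            fixture_model.muscle_names,
                            fixture_model.marker_names)
    back = read_reference_dataset(tmp_path)
    np.testing.assert_allclose(back.q, fixture_reference.q, atol=1e-9)
    np.testing.assert_allclose(back.markers, fixture_reference.markers,
                               atol=1e-9)
    np.testing.assert_allclose(back.forces, fixture_reference.forces,
                               atol=1e-6)
    assert back.cocontraction == fixture_reference.cocontraction
    assert back.model_hash == fixture_reference.model_hash
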