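"""Moving-horizon estimator: recovery, dynamic consistency, mechanics."""

from __future__ import annotations

import numpy as np
import pytest

from myomhe.mhe import (CostWeights, MeasurementStream, MheProblem,
                        delay_emg, run_mhe, subsample_stream)
from myomhe.model import integrate_interval
from myomhe.ocp import BufferingError


def test_noiseless_recovery(fixture_cm, fixture_reference,
                            fixture_noiseless_mhe):
    """Window-7 excitation-driven MHE on self-generated noiseless data
    recovers angles, forces and markers almost exactly."""
    ds = fixture_reference
    res = fixture_noiseless_mhe
    S = len(res.time)
    nq = fixture_cm.nq
    q_rmse = np.degrees(np.sqrt(((res.q(nq) - ds.q[:S]) ** 2).mean()))
    f_rmse = np.sqrt(((res.forces - ds.forces[:S]) ** 2).mean())
    mk = fixture_cm.marker_positions(res.q(nq))
    mk_rmse = np.sqrt(((mk - ds.markers[:S]) ** 2).mean())
    assert q_rmse < 0.01                      # deg
    assert f_rmse < 1.0                       # N
    assert mk_rmse * 1000 < 0.01              # mm
    assert res.convergence_rate > 0.90
    assert res.achieved


def test_stored_chain_is_dynamically_consistent(fixture_cm,
                                                fixture_noiseless_mhe):
    """One-step integration residual of the stored (x, u) sequence is
    below 1e-6: the headline property of the estimator."""
    res = fixture_noiseless_mhe
    dt = float(res.time[1] - res.time[0])
    x, u = res.states, res.controls
    phi = integrate_interval(fixture_cm, x[:-1], u[:-1], dt, 1)
    resid = np.abs(x[1:] - phi).max()
    assert resid < 1e-6


def test_bound_compliance(fixture_cm, fixture_noiseless_mhe):
    res = fixture_noiseless_mhe
    nq = fixture_cm.nq
    assert res.controls.min() >= -1e-8
    assert res.controls.max() <= 1 + 1e-8
    q = res.q(nq)
    assert np.all(q >= fixture_cm.q_lower - 1e-8)
    assert np.all(q <= fixture_cm.q_upper + 1e-8)
    a = res.states[:, 2 * nq:]
    assert a.min() >= -1e-8 and a.max() <= 1 + 1e-8


def test_warm_start_reduces_iterations(fixture_noiseless_mhe):
    """Median warm-started iteration count is below the cold first
    solve: the premise of the moving-horizon speedup."""
    res = fixture_noiseless_mhe
    assert np.median(res.iterations[1:]) < res.iterations[0]


def test_determinism(fixture_cm, fixture_reference):
    from myomhe.mhe import run_mhe

    stream = MeasurementStream.from_reference(fixture_reference)
    sub = subsample_stream(stream, 4)
    p = MheProblem(window=5, n_substeps=4)
    a = run_mhe(fixture_cm, sub, p)
    b = run_mhe(fixture_cm, sub, p)
    np.testing.assert_array_equal(a.states, b.states)
    np.testing.assert_array_equal(a.controls, b.controls)
    np.testing.assert_array_equal(a.converged, b.converged)


def test_subsample_arithmetic(fixture_reference):
    stream = MeasurementStream.from_reference(fixture_reference)
    assert len(subsample_stream(stream, 1)) == len(stream)
    sub = subsample_stream(stream, 4)
    assert len(sub) == int(np.ceil(len(stream) / 4))
    assert sub.dt == pytest.approx(4 * stream.dt)
    np.testing.assert_array_equal(sub.emg, stream.emg[::4])
    with pytest.raises(ValueError):
        subsample_stream(stream, 0)


def test_emg_delay_shift(fixture_reference):
    stream = MeasurementStream.from_reference(fixture_reference)
    delayed = delay_emg(stream, 2.5 * stream.dt)   # rounds to 2 frames
    np.testing.assert_array_equal(delayed.emg[2:], stream.emg[:-2])
    np.testing.assert_array_equal(delayed.emg[0], stream.emg[0])
    np.testing.assert_array_equal(delayed.markers, stream.markers)


def test_channel_mismatch_rejected(fixture_cm, fixture_reference):
    ds = fixture_reference
    bad = MeasurementStream(time=ds.time.copy(),
                            markers=ds.markers.copy(),
                            emg=ds.excitations[:, :-1].copy())
    with pytest.raises(ValueError):
        run_mhe(fixture_cm, bad, MheProblem(window=5))


def test_stream_shorter_than_window_rejected(fixture_cm,
                                             fixture_reference):
    ds = fixture_reference
    short = MeasurementStream(time=ds.time[:5].copy(),
                              markers=ds.markers[:5].copy(),
                              emg=ds.excitations[:5].copy())
    with pytest.raises(BufferingError):
        run_mhe(fixture_cm, short, MheProblem(window=7))


def test_activation_driven_formulation_runs(fixture_cm, fixture_reference):
    """The simpler formulation (activations as controls, delayed EMG)
    also tracks the reference closely."""
    stream = subsample_stream(
        MeasurementStream.from_reference(fixture_reference), 2)
    p = MheProblem(window=7, formulation="activation_driven", n_substeps=2)
    res = run_mhe(fixture_cm, stream, p)
    assert res.convergence_rate > 0.9
    S = len(res.time)
    nq = fixture_cm.nq
    ie = np.searchsorted(fixture_reference.time, res.time)
    q_rmse = np.degrees(np.sqrt(
        ((res.q(nq) - fixture_reference.q[ie]) ** 2).mean()))
    assert q_rmse < 0.1


def test_min_excitation_variant_runs(fixture_cm, fixture_reference):
    stream = subsample_stream(
        MeasurementStream.from_reference(fixture_reference), 4)
    p = MheProblem(window=7,
                   weights=CostWeights(variant="min_excitation"),
                   n_substeps=4)
    res = run_mhe(fixture_cm, stream, p)
    assert res.convergence_rate >= 0.75
    assert res.controls.min() >= -1e-9


def test_cost_variant_marker_weights():
    assert CostWeights(variant="track_emg_high_marker").w_markers == 1e9
    assert CostWeights(variant="track_emg_low_marker").w_markers == 1e7
    assert not CostWeights(variant="min_excitation").tracks_emg
    with pytest.raises(ValueError):
        CostWeights(variant="bogus")
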