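"""Noise simulator: Fourier-domain EMG noise and marker placement error."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import gamma

from myomhe.noise import (EMG_NOISE_STD, MARKER_NOISE_STD, NoiseSpec,
                          corrupt_dataset, corrupt_emg,
                          corrupt_marker_placement, resimulate_markers)

RATE = 100.0


def _clean_signal(T=200, channels=6, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(T) / RATE
    base = 0.25 + 0.15 * np.sin(2 * np.pi * 0.5 * t)[:, None]
    return np.clip(base + 0.05 * rng.random((T, channels)), 0, 1)


def test_level_none_is_bit_identical():
    exc = _clean_signal()
    out = corrupt_emg(exc, RATE, NoiseSpec(emg_level="none"), seed=3)
    assert np.array_equal(out, exc)


def test_fft_roundtrip_identity():
    """Zero perturbation through the transform reproduces the signal."""
    exc = _clean_signal()
    back = np.fft.irfft(np.fft.rfft(exc, axis=0), n=len(exc), axis=0)
    assert np.abs(back - exc).max() < 1e-12


def test_noise_is_band_limited():
    """Added power above the cutoff is < 1% (clipping leakage only),
    over 30 seeded draws."""
    exc = _clean_signal()
    spec = NoiseSpec(emg_level="mid")
    freqs = np.fft.rfftfreq(len(exc), 1 / RATE)
    leak = []
    for seed in range(30):
        noisy = corrupt_emg(exc, RATE, spec, seed)
        d = np.fft.rfft(noisy - exc, axis=0)
        p = np.abs(d) ** 2
        leak.append(p[freqs > spec.emg_cutoff_hz].sum() / p.sum())
    assert max(leak) < 0.01


def test_noise_magnitude_increases_with_level():
    """Mean squared corruption strictly increases none->low->mid->high
    (30 seeded draws)."""
    exc = _clean_signal()
    mse = {}
    for level in ("none", "low", "mid", "high"):
        spec = NoiseSpec(emg_level=level)
        vals = [np.mean((corrupt_emg(exc, RATE, spec, s) - exc) ** 2)
                for s in range(30)]
        mse[level] = np.mean(vals)
    assert mse["none"] < mse["low"] < mse["mid"] < mse["high"]


def test_output_in_unit_interval_and_input_untouched():
    exc = _clean_signal()
    before = exc.copy()
    out = corrupt_emg(exc, RATE, NoiseSpec(emg_level="high"), 11)
    assert out.min() >= 0.0 and out.max() <= 1.0
    assert np.array_equal(exc, before)


def test_same_seed_reproduces_bit_exactly():
    exc = _clean_signal()
    spec = NoiseSpec(emg_level="high")
    a = corrupt_emg(exc, RATE, spec, 42)
    b = corrupt_emg(exc, RATE, spec, 42)
    assert np.array_equal(a, b)
    c = corrupt_emg(exc, RATE, spec, 43)
    assert not np.array_equal(a, c)


# ------------------------------------------------------- marker placement
def test_placement_none_is_identity(fixture_model):
    surrogate, off = corrupt_marker_placement(fixture_model, "none", 1)
    assert np.all(off == 0)
    assert surrogate.content_hash() == fixture_model.content_hash()


def test_placement_norm_matches_chi_distribution(fixture_model):
    """Mean displacement norm over 1000 draws at sigma = 10 mm within
    10% of the closed-form 3-D Gaussian norm mean."""
    sigma = MARKER_NOISE_STD["high"]
    norms = []
    for seed in range(250):  # 250 draws x 4 markers = 1000 samples
        _, off = corrupt_marker_placement(fixture_model, "high", seed)
        norms.extend(np.linalg.norm(off, axis=1))
    per_axis = sigma / np.sqrt(3.0)
    expected = per_axis * np.sqrt(2.0) * gamma(2.0) / gamma(1.5)
    assert len(norms) == 1000
    assert abs(np.mean(norms) - expected) / expected < 0.10


def test_placement_offsets_constant_over_time(fixture_model):
    """Placement error is a rigid offset, not per-frame jitter: for a
    rotation-only frame the global displacement norm is constant and
    equals the local offset norm."""
    from myomhe.model import CompiledModel

    surrogate, off = corrupt_marker_placement(fixture_model, "mid", 5)
    q_traj = np.column_stack([np.linspace(0.2, 1.2, 40),
                              np.linspace(0.5, 1.8, 40)])
    noisy = resimulate_markers(surrogate, q_traj)
    clean = resimulate_markers(fixture_model, q_traj)
    d = np.linalg.norm(noisy - clean, axis=2)     # (T, n_markers)
    expected = np.broadcast_to(np.linalg.norm(off, axis=1), d.shape)
    np.testing.assert_allclose(d, expected, atol=1e-12)


def test_surrogate_identity_reproduces_reference_markers(
        fixture_cm, fixture_reference):
    traj = resimulate_markers(fixture_cm, fixture_reference.q)
    np.testing.assert_allclose(traj, fixture_reference.markers, atol=1e-12)
    assert traj.shape == (fixture_reference.n_frames,
                          fixture_cm.n_markers, 3)


def test_corrupt_dataset_keeps_ground_truth(fixture_model,
                                            fixture_reference):
    ds = fixture_reference
    exc_before = ds.excitations.copy()
    mk_before = ds.markers.copy()
    out = corrupt_dataset(fixture_model, ds,
                          NoiseSpec(emg_level="mid", marker_level="mid"),
                          seed=9)
    assert np.array_equal(ds.excitations, exc_before)
    assert np.array_equal(ds.markers, mk_before)
    assert out["emg"].shape == ds.excitations.shape
    assert out["markers"].shape == ds.markers.shape
    # deterministic given the seed
    out2 = corrupt_dataset(fixture_model, ds,
                           NoiseSpec(emg_level="mid", marker_level="mid"),
                           seed=9)
    assert np.array_equal(out["emg"], out2["emg"])
    assert np.array_equal(out["markers"], out2["markers"])


def test_invalid_levels_rejected():
    with pytest.raises(ValueError):
        NoiseSpec(emg_level="extreme")
    with pytest.raises(ValueError):
        NoiseSpec(emg_cutoff_hz=-1.0)
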