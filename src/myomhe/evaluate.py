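"""Evaluation campaign: RMSE scoring, window sweep, noise grid, ANOVA.

The estimator is scored against the generating reference by pooled
root-mean-square error on joint angles (deg), muscle forces (N) and
marker positions (m), computed on the frames where estimate and
reference share timestamps.  The full campaign crosses marker noise x
EMG noise x co-contraction (4 levels each, 64 cells) with seeded
repetitions; trials whose window-solve convergence rate is at or below
90% are flagged and excluded from the statistics, mirroring how such
simulation studies filter unconverged trials.  Fixed-effects ANOVAs
(statsmodels) with Bonferroni-corrected pairwise post-hoc t-tests
summarize the factor effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .mhe import (CostWeights, EstimationResult, MeasurementStream,
                  MheProblem, full_window_estimate, run_mhe,
                  subsample_stream)
from .model.kinematics import CompiledModel
from .model.types import MusculoskeletalModel
from .noise import LEVELS, NoiseSpec, corrupt_dataset
from .reference import ReferenceDataset

KEEP_THRESHOLD = 0.90  # trials must exceed this convergence rate


class AlignmentError(ValueError):
    """Estimate and reference share no timestamps."""


def _align(t_est: np.ndarray, t_ref: np.ndarray):
    """Index pairs of (near-)equal timestamps (inner join on the grid)."""
    i = np.searchsorted(t_ref, t_est)
    i = np.clip(i, 0, len(t_ref) - 1)
    left = np.clip(i - 1, 0, len(t_ref) - 1)
    use_left = np.abs(t_ref[left] - t_est) < np.abs(t_ref[i] - t_est)
    j = np.where(use_left, left, i)
    tol = 1e-9 + 1e-6 * max(1.0, float(np.abs(t_ref).max()))
    ok = np.abs(t_ref[j] - t_est) <= tol
    if not ok.any():
        raise AlignmentError("no overlapping timestamps between estimate "
                             "and reference")
    return np.nonzero(ok)[0], j[ok]


def rmse(estimated: np.ndarray, reference: np.ndarray,
         t_est: np.ndarray | None = None,
         t_ref: np.ndarray | None = None) -> float:
    """Pooled RMSE over channels and time.

    With timestamps given, rows are first matched by an inner join on
    the time grid; otherwise arrays must already be aligned.
    """
    estimated = np.asarray(estimated, float)
    reference = np.asarray(reference, float)
    if t_est is not None and t_ref is not None:
        ie, ir = _align(np.asarray(t_est, float), np.asarray(t_ref, float))
        estimated = estimated[ie]
        reference = reference[ir]
    if estimated.shape != reference.shape:
        raise AlignmentError(
            f"shape mismatch {estimated.shape} vs {reference.shape}")
    return float(np.sqrt(np.mean((estimated - reference) ** 2)))


def score_estimate(cm: CompiledModel, result: EstimationResult,
                   ds: ReferenceDataset) -> dict:
    """Joint-angle (deg), force (N) and marker (m) RMSE of one run."""
    nq = cm.nq
    ie, ir = _align(result.time, ds.time)
    q_est = result.states[ie, :nq]
    markers_est = cm.marker_positions(q_est)
    return {
        "rmse_q_deg": rmse(np.degrees(q_est), np.degrees(ds.q[ir])),
        "rmse_force_n": rmse(result.forces[ie], ds.forces[ir]),
        "rmse_markers_m": rmse(markers_est, ds.markers[ir]),
        "convergence_rate": result.convergence_rate,
        "kept": result.convergence_rate > KEEP_THRESHOLD,
    }


# ------------------------------------------------------------ window sweep
def realtime_subsample_factor(window: int) -> int:
    """Emulated real-time subsampling for a given window size.

    Mirrors an estimator whose solve rate falls roughly linearly from
    about 30 Hz at window 3 to about 10 Hz at window 20 on a 100 Hz
    stream: the larger the window, the fewer frames it can ingest.
    """
    rate = 30.0 - (20.0 / 17.0) * (window - 3)
    return max(1, int(round(100.0 / rate)))


def window_sweep(model: MusculoskeletalModel | CompiledModel,
                 ds: ReferenceDataset, sizes=range(3, 21),
                 formulations=("excitation_driven",),
                 weights: CostWeights | None = None,
                 subsample=realtime_subsample_factor,
                 include_full_window: bool = False,
                 n_substeps_per_frame: int = 1) -> pd.DataFrame:
    """RMSE versus window size on noiseless data (plus optional
    full-window baseline rows)."""
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    stream0 = MeasurementStream.from_reference(ds)
    rows = []
    for form in formulations:
        for w in sizes:
            k = subsample(w) if callable(subsample) else int(subsample)
            stream = subsample_stream(stream0, k)
            if len(stream) <= w:
                continue
            problem = MheProblem(
                window=int(w), formulation=form,
                weights=weights or CostWeights(),
                n_substeps=k * n_substeps_per_frame)
            try:
                result = run_mhe(cm, stream, problem)
                score = score_estimate(cm, result, ds)
            except Exception as exc:  # keep sweeping, record the failure
                rows.append({"window": int(w), "formulation": form,
                             "subsample": k, "error": str(exc)})
                continue
            rows.append({"window": int(w), "formulation": form,
                         "subsample": k, **score})
        if include_full_window:
            stream = subsample_stream(stream0, 1)
            result = full_window_estimate(cm, stream,
                                          weights or CostWeights(), form)
            score = score_estimate(cm, result, ds)
            rows.append({"window": 0, "formulation": form,
                         "subsample": 1, **score})
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- grid
@dataclass
class ExperimentGrid:
    """Fully crossed noise x co-contraction design."""

    marker_levels: tuple = LEVELS
    emg_levels: tuple = LEVELS
    cocontraction_levels: tuple = LEVELS
    repetitions: int = 30
    variants: tuple = ("track_emg_high_marker", "min_excitation")
    formulation: str = "excitation_driven"
    window: int = 7
    subsample: int = 4
    base_seed: int = 0

    def cells(self):
        for mk in self.marker_levels:
            for emg in self.emg_levels:
                for co in self.cocontraction_levels:
                    yield mk, emg, co

    def cell_seed(self, marker_level: str, emg_level: str,
                  cocontraction: str, repetition: int) -> int:
        """Unique deterministic seed per (cell, repetition)."""
        key = (LEVELS.index(marker_level) * 4 + LEVELS.index(emg_level)) * 4 \
            + LEVELS.index(cocontraction)
        return int(np.random.SeedSequence(
            [self.base_seed, key, repetition]).generate_state(1)[0]
            % (2 ** 31))


def run_grid(grid: ExperimentGrid,
             model: MusculoskeletalModel | CompiledModel,
             references: dict,
             n_substeps_per_frame: int = 1,
             progress=None) -> pd.DataFrame:
    """Score table of the crossed experiment.

    ``references`` maps co-contraction level -> ReferenceDataset (all
    levels used by the grid must be present).  One noise draw is made
    per (cell, repetition) from that cell's seed; each requested cost
    variant is then run on the same corrupted data at the grid's window
    size.  Deterministic given ``grid.base_seed``.
    """
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    missing = [co for co in grid.cocontraction_levels if co not in references]
    if missing:
        raise ValueError(f"missing reference datasets for levels {missing}")
    rows = []
    for mk, emg, co in grid.cells():
        ds = references[co]
        for rep in range(grid.repetitions):
            seed = grid.cell_seed(mk, emg, co, rep)
            spec = NoiseSpec(emg_level=emg, marker_level=mk)
            noisy = corrupt_dataset(cm.model, ds, spec, seed)
            stream = MeasurementStream(time=ds.time.copy(),
                                       markers=noisy["markers"],
                                       emg=noisy["emg"])
            stream = subsample_stream(stream, grid.subsample)
            for variant in grid.variants:
                problem = MheProblem(
                    window=grid.window, formulation=grid.formulation,
                    weights=CostWeights(variant=variant),
                    n_substeps=grid.subsample * n_substeps_per_frame)
                row = {"marker_noise": mk, "emg_noise": emg,
                       "cocontraction": co, "repetition": rep,
                       "variant": variant, "seed": seed}
                try:
                    result = run_mhe(cm, stream, problem)
                    row.update(score_estimate(cm, result, ds))
                except Exception as exc:
                    row.update({"error": str(exc), "kept": False})
                rows.append(row)
                if progress is not None:
                    progress(row)
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- anova
def _check_factors(table: pd.DataFrame, factors):
    for f in factors:
        if f not in table.columns:
            raise ValueError(f"factor {f!r} not in table")
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")


def _kept(table: pd.DataFrame) -> pd.DataFrame:
    if "kept" in table.columns:
        return table[table["kept"].astype(bool)]
    return table


def anova(table: pd.DataFrame, response: str, factors,
          alpha: float = 0.001) -> dict:
    """Fixed-effects factorial ANOVA with Bonferroni post-hoc t-tests.

    Returns ``{"anova": DataFrame, "posthoc": DataFrame}``.  The
    post-hoc table compares the levels of each main factor pairwise
    (Welch t-tests) at the Bonferroni-adjusted threshold alpha / m.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats

    table = _kept(table).copy()
    _check_factors(table, factors)
    if response not in table.columns:
        raise ValueError(f"response {response!r} not in table")
    terms = " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(f"{response} ~ {terms}", data=table).fit()
    anova_tab = sm.stats.anova_lm(fit, typ=2)

    rows = []
    n_tests = sum(len(list(combinations(table[f].unique(), 2)))
                  for f in factors)
    for f in factors:
        for a, b in combinations(sorted(table[f].unique()), 2):
            xa = table.loc[table[f] == a, response]
            xb = table.loc[table[f] == b, response]
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append({"factor": f, "level_a": a, "level_b": b,
                         "t": t, "p": p,
                         "p_bonferroni": min(1.0, p * n_tests),
                         "significant": p * n_tests < alpha})
    return {"anova": anova_tab, "posthoc": pd.DataFrame(rows),
            "alpha": alpha, "n_tests": n_tests}


def anova_two_way(table: pd.DataFrame, response: str = "rmse_force_n",
                  factors=("emg_noise", "cocontraction"),
                  alpha: float = 0.001) -> dict:
    """Two-way ANOVA: EMG noise x co-contraction on force RMSE."""
    return anova(table, response, list(factors), alpha)


def anova_three_way(table: pd.DataFrame, response: str = "rmse_q_deg",
                    factors=("marker_noise", "emg_noise", "variant"),
                    alpha: float = 0.001) -> dict:
    """Three-way ANOVA: marker noise x EMG noise x cost variant on
    joint-angle RMSE."""
    return anova(table, response, list(factors), alpha)
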