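"""Readers and writers for the plain-text interchange formats.

Markers travel as wide CSV (time plus three columns per marker,
``<name>_x|_y|_z``, meters), EMG envelopes as CSV (time plus one column
per muscle element), trajectories (states, controls, forces) as CSV with
one column per channel, models as YAML, and run metadata as JSON
sidecars.  Every file starts with an explicit header; a units comment
line (prefixed ``#``) precedes it.  All writes are atomic (temp file +
rename) so interrupted runs never leave half-written outputs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .mhe import EstimationResult, MeasurementStream
from .reference import ReferenceDataset


class SchemaError(ValueError):
    """A file does not match the documented schema."""


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


def _write_csv(path: Path, df: pd.DataFrame, units_comment: str) -> None:
    text = f"# {units_comment}\n" + df.to_csv(index=False)
    _atomic_write_text(path, text)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ----------------------------------------------------------------- markers
def write_markers(path: str | Path, time: np.ndarray, markers: np.ndarray,
                  labels: list[str]) -> None:
    """Wide marker CSV: time_s then <label>_x/_y/_z in meters."""
    markers = np.asarray(markers, float)
    if markers.shape[1:] != (len(labels), 3):
        raise SchemaError(f"markers must be (T, {len(labels)}, 3)")
    cols = {"time_s": np.asarray(time, float)}
    for i, name in enumerate(labels):
        for j, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = markers[:, i, j]
    _write_csv(Path(path), pd.DataFrame(cols),
               "units: time_s in s, marker coordinates in m")


def read_markers(path: str | Path, expected_labels: list[str] | None = None
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a marker CSV; returns (time, markers (T, M, 3), labels).

    With ``expected_labels``, file columns are reconciled against them
    and reordered as needed; missing labels raise ``SchemaError``.
    """
    df = _read_csv(Path(path))
    if "time_s" not in df.columns:
        raise SchemaError("marker CSV needs a time_s column")
    suffixes = ("_x", "_y", "_z")
    labels = []
    for c in df.columns:
        if c.endswith("_x"):
            base = c[:-2]
            if all(f"{base}{s}" in df.columns for s in suffixes):
                labels.append(base)
    if not labels:
        raise SchemaError("no <label>_x/_y/_z column triplets found")
    if expected_labels is not None:
        missing = [l for l in expected_labels if l not in labels]
        if missing:
            raise SchemaError(f"missing marker labels: {missing}")
        labels = list(expected_labels)
    T = len(df)
    out = np.empty((T, len(labels), 3))
    for i, name in enumerate(labels):
        for j, ax in enumerate("xyz"):
            out[:, i, j] = df[f"{name}_{ax}"].to_numpy(float)
    return df["time_s"].to_numpy(float), out, labels


# --------------------------------------------------------------------- EMG
def write_emg(path: str | Path, time: np.ndarray, emg: np.ndarray,
              channels: list[str]) -> None:
    emg = np.asarray(emg, float)
    if emg.shape[1] != len(channels):
        raise SchemaError(f"emg must be (T, {len(channels)})")
    df = pd.DataFrame({"time_s": np.asarray(time, float),
                       **{c: emg[:, i] for i, c in enumerate(channels)}})
    _write_csv(Path(path), df,
               "units: time_s in s, envelopes dimensionless in [0, 1]")


def read_emg(path: str | Path, expected_channels: list[str] | None = None
             ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read an EMG CSV; validates the [0, 1] range.

    Values within [-0.01, 1.01] are clipped with a warning; values
    beyond that are a hard error.  Channel order is reconciled with
    ``expected_channels`` when given.
    """
    df = _read_csv(Path(path))
    if "time_s" not in df.columns:
        raise SchemaError("EMG CSV needs a time_s column")
    time = df["time_s"].to_numpy(float)
    if np.any(np.diff(time) <= 0):
        raise SchemaError("EMG timestamps must be strictly increasing")
    channels = [c for c in df.columns if c != "time_s"]
    if expected_channels is not None:
        unknown = [c for c in channels if c not in expected_channels]
        missing = [c for c in expected_channels if c not in channels]
        if unknown or missing:
            raise SchemaError(f"channel mismatch: unknown {unknown}, "
                              f"missing {missing}")
        channels = list(expected_channels)
    emg = df[channels].to_numpy(float)
    if emg.min() < -0.01 or emg.max() > 1.01:
        raise SchemaError("EMG values outside [-0.01, 1.01]")
    if emg.min() < 0.0 or emg.max() > 1.0:
        warnings.warn("EMG values slightly outside [0, 1]; clipping",
                      stacklevel=2)
        emg = np.clip(emg, 0.0, 1.0)
    return time, emg, channels


# ------------------------------------------------------------ trajectories
def write_trajectory(path: str | Path, time: np.ndarray, data: np.ndarray,
                     columns: list[str], units: str) -> None:
    df = pd.DataFrame({"time_s": np.asarray(time, float),
                       **{c: np.asarray(data, float)[:, i]
                          for i, c in enumerate(columns)}})
    _write_csv(Path(path), df, f"units: time_s in s, values in {units}")


def read_trajectory(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    df = _read_csv(Path(path))
    return df["time_s"].to_numpy(float), df.drop(columns=["time_s"])


# ---------------------------------------------------------------- sidecars
def write_sidecar(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    _atomic_write_text(Path(path),
                       json.dumps(payload, indent=2, default=_default))


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# --------------------------------------------------- dataset / result dirs
def write_reference_dataset(ds: ReferenceDataset, out_dir: str | Path,
                            muscle_names: list[str] | None = None,
                            marker_names: list[str] | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    M = ds.excitations.shape[1]
    mus = muscle_names or [f"muscle_{i}" for i in range(M)]
    mks = marker_names or [f"marker_{i}" for i in range(ds.markers.shape[1])]
    nq = ds.q.shape[1]
    jn = [f"q{i}" for i in range(nq)]
    write_trajectory(out / "q.csv", ds.time, ds.q, jn, "rad")
    write_trajectory(out / "qdot.csv", ds.time, ds.qdot,
                     [f"qd{i}" for i in range(nq)], "rad/s")
    write_trajectory(out / "activations.csv", ds.time, ds.activations,
                     mus, "dimensionless [0, 1]")
    write_trajectory(out / "excitations.csv", ds.time, ds.excitations,
                     mus, "dimensionless [0, 1]")
    write_trajectory(out / "forces.csv", ds.time, ds.forces, mus, "N")
    write_markers(out / "markers.csv", ds.time, ds.markers, mks)
    write_sidecar(out / "reference.json", {
        "cocontraction": ds.cocontraction, "model_hash": ds.model_hash,
        "config": ds.config, "n_frames": ds.n_frames, "dt": ds.dt})


def read_reference_dataset(in_dir: str | Path) -> ReferenceDataset:
    d = Path(in_dir)
    meta = read_sidecar(d / "reference.json")
    time, q = read_trajectory(d / "q.csv")
    _, qdot = read_trajectory(d / "qdot.csv")
    _, act = read_trajectory(d / "activations.csv")
    _, exc = read_trajectory(d / "excitations.csv")
    _, forces = read_trajectory(d / "forces.csv")
    _, markers, _ = read_markers(d / "markers.csv")
    return ReferenceDataset(
        time=time, q=q.to_numpy(), qdot=qdot.to_numpy(),
        activations=act.to_numpy(), excitations=exc.to_numpy(),
        forces=forces.to_numpy(), markers=markers,
        cocontraction=meta["cocontraction"],
        model_hash=meta["model_hash"], config=meta["config"])


def write_estimation_result(res: EstimationResult, out_dir: str | Path,
                            muscle_names: list[str] | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nx = res.states.shape[1]
    M = res.forces.shape[1]
    mus = muscle_names or [f"muscle_{i}" for i in range(M)]
    write_trajectory(out / "states.csv", res.time, res.states,
                     [f"x{i}" for i in range(nx)], "rad, rad/s, [0, 1]")
    write_trajectory(out / "controls.csv", res.time, res.controls, mus,
                     "dimensionless [0, 1]")
    write_trajectory(out / "forces.csv", res.time, res.forces, mus, "N")
    write_sidecar(out / "run.json", {
        "config": res.config,
        "convergence_rate": res.convergence_rate,
        "achieved": res.achieved,
        "converged": res.converged,
        "iterations": res.iterations,
        "solve_seconds_total": float(res.solve_seconds.sum()),
    })


def stream_from_files(markers_path: str | Path, emg_path: str | Path,
                      marker_labels: list[str] | None = None,
                      emg_channels: list[str] | None = None
                      ) -> MeasurementStream:
    """Assemble a measurement stream from marker + EMG CSV files."""
    t_m, markers, _ = read_markers(markers_path, marker_labels)
    t_e, emg, _ = read_emg(emg_path, emg_channels)
    if len(t_m) != len(t_e) or np.abs(t_m - t_e).max() > 1e-9:
        raise SchemaError("marker and EMG time grids differ")
    return MeasurementStream(time=t_m, markers=markers, emg=emg)
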