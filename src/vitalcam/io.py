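"""File interchange: thermal stacks, traces, calibrations and reports.

Formats are deliberately plain: thermal sequences as ``.npz`` array
containers, detections / ground truth / calibrations / reports as JSON, and
time-series traces as CSV. Every schema carries a version tag and readers
validate columns and time monotonicity, so a malformed input fails loudly
with the offending field named.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pulse import ChannelTraces
from .respiration import BreathSignal, ThermalSequence

__all__ = [
    "save_thermal_sequence",
    "load_thermal_sequence",
    "save_breath_trace",
    "load_breath_trace",
    "save_channel_traces",
    "load_channel_traces",
]


def save_thermal_sequence(seq: ThermalSequence, path: str | Path) -> None:
    np.savez_compressed(path, frames=seq.frames, fs=np.asarray(seq.fs))


def load_thermal_sequence(path: str | Path) -> ThermalSequence:
    with np.load(path) as z:
        if "frames" not in z or "fs" not in z:
            raise ValueError("thermal sequence file must contain 'frames' and 'fs'")
        return ThermalSequence(z["frames"], float(z["fs"]))


def _check_time_column(t: np.ndarray, path: str | Path) -> None:
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column 't_s' must be strictly increasing")


def _check_columns(df: pd.DataFrame, expected: list[str], path: str | Path) -> None:
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValueError(f"{path}: unknown column(s) {unknown}; expected {expected}")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def save_breath_trace(sig: BreathSignal, path: str | Path) -> None:
    pd.DataFrame({"t_s": sig.time(), "value": sig.values}).to_csv(path, index=False)


def load_breath_trace(path: str | Path, fs: float | None = None) -> BreathSignal:
    """Read a (t_s, value) CSV; the rate is inferred from the time column
    unless given explicitly."""
    df = pd.read_csv(path)
    _check_columns(df, ["t_s", "value"], path)
    t = df["t_s"].to_numpy(dtype=float)
    _check_time_column(t, path)
    if fs is None:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError(f"{path}: irregular sampling; pass fs explicitly")
        fs = 1.0 / dt[0]
    return BreathSignal(df["value"].to_numpy(dtype=float), fs, t0=float(t[0]))


def save_channel_traces(traces: ChannelTraces, path: str | Path) -> None:
    t = np.arange(traces.n) / traces.fs
    pd.DataFrame({"t_s": t, "r": traces.r, "g": traces.g, "b": traces.b}).to_csv(
        path, index=False
    )


def load_channel_traces(path: str | Path, fs: float | None = None) -> ChannelTraces:
    df = pd.read_csv(path)
    _check_columns(df, ["t_s", "r", "g", "b"], path)
    t = df["t_s"].to_numpy(dtype=float)
    _check_time_column(t, path)
    if fs is None:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError(f"{path}: irregular sampling; pass fs explicitly")
        fs = 1.0 / dt[0]
    return ChannelTraces(
        df["r"].to_numpy(dtype=float),
        df["g"].to_numpy(dtype=float),
        df["b"].to_numpy(dtype=float),
        fs,
    )
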