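"""Readers and writers for the package's tabular and signal formats.

All formats are plain text or raw float32: spike tables, behavioral event
logs and waveform-feature tables are CSV; LFP traces are either CSV
(time_s, value) or raw float32 with a JSON sidecar carrying the sampling
rate and start time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lfp import LfpTrace

__all__ = [
    "read_spikes", "write_spikes",
    "read_events", "write_events",
    "read_features", "write_features",
    "read_lfp", "write_lfp",
    "write_sim_spikes",
]

_SPIKE_COLS = ["unit_id", "time_s"]
_EVENT_COLS = ["session", "target", "side", "start_s", "end_s"]
_FEATURE_COLS = ["unit_id", "ratio", "width_us", "rate_hz"]


def _read_csv(path: str | Path, cols: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_spikes(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, _SPIKE_COLS)


def write_spikes(df: pd.DataFrame, path: str | Path) -> None:
    df[_SPIKE_COLS].to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, _EVENT_COLS)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df[_EVENT_COLS].to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, _FEATURE_COLS)


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    df[_FEATURE_COLS].to_csv(path, index=False)


def write_lfp(trace: LfpTrace, path: str | Path) -> None:
    """Write an LFP trace as raw float32 plus a JSON metadata sidecar."""
    path = Path(path)
    np.asarray(trace.samples, dtype=np.float32).tofile(path)
    meta = {"fs": trace.fs, "t0": trace.t0, "n_samples": len(trace.samples),
            "dtype": "float32"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_lfp(path: str | Path) -> LfpTrace:
    """Read an LFP trace from raw float32 + sidecar, or from CSV."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        fs = 1.0 / np.median(np.diff(t))
        return LfpTrace(df["value"].to_numpy(float), float(fs), float(t[0]))
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"LFP sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    x = np.fromfile(path, dtype=np.float32).astype(float)
    return LfpTrace(x, float(meta["fs"]), float(meta.get("t0", 0.0)))


def write_sim_spikes(result, path: str | Path) -> None:
    """Write simulator output as (neuron_id, spike_time_ms) CSV."""
    rows = []
    for i, t in enumerate(result.spike_times):
        for x in t:
            rows.append((i, x))
    pd.DataFrame(rows, columns=["neuron_id", "spike_time_ms"]).to_csv(
        path, index=False)
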