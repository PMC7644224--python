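"""CSV readers/writers for the package's declared file dialects.

Trajectory files: columns ``worm_id, frame, time_s, x_mm, y_mm`` (frame
0-based, positions in mm).  Calcium files: ``time_s, fluorescence_au``
with optional ``temperature_C`` and ``neuron_id`` columns (a file without
``neuron_id`` holds a single trace).  Ground truth is written to separate
files, never merged into data files.  Round trips preserve positions to
1e-4 mm and fluorescence to 1e-4 au.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .calcium_quant import CalciumTrace
from .synthetic_worlds import GroundTruth
from .track_quant import Trajectory

__all__ = [
    "SchemaError",
    "read_trajectories",
    "write_trajectories",
    "read_traces",
    "write_traces",
    "write_ground_truth",
]

TRAJ_COLUMNS = ["worm_id", "frame", "time_s", "x_mm", "y_mm"]
TRACE_COLUMNS = ["time_s", "fluorescence_au"]


class SchemaError(ValueError):
    """Raised when a CSV file does not match the declared dialect."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _infer_frame_rate(times: np.ndarray, path, worm_id) -> float:
    dt = np.diff(times)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 1
        raise SchemaError(
            f"{path}: non-monotone time for worm {worm_id!r} near row {bad}"
        )
    return 1.0 / float(np.median(dt))


def read_trajectories(path) -> List[Trajectory]:
    """Read a trajectory CSV; rows are re-sorted by (worm_id, frame) if needed."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRAJ_COLUMNS, path)
    sorted_df = df.sort_values(["worm_id", "frame"], kind="stable")
    if not sorted_df.index.equals(df.index):
        warnings.warn(f"{path}: rows out of order; re-sorted by (worm_id, frame)", stacklevel=2)
    trajectories = []
    for worm_id, grp in sorted_df.groupby("worm_id", sort=True):
        times = grp["time_s"].to_numpy(dtype=float)
        fr = _infer_frame_rate(times, path, worm_id)
        trajectories.append(
            Trajectory(
                worm_id=str(worm_id),
                times=times,
                x=grp["x_mm"].to_numpy(dtype=float),
                y=grp["y_mm"].to_numpy(dtype=float),
                frame_rate=fr,
                frames=grp["frame"].to_numpy(dtype=int),
            )
        )
    if not trajectories:
        raise SchemaError(f"{path}: no trajectory rows")
    return trajectories


def write_trajectories(trajectories: Sequence[Trajectory], path) -> None:
    rows = []
    for traj in trajectories:
        rows.append(
            pd.DataFrame(
                {
                    "worm_id": traj.worm_id,
                    "frame": traj.frames,
                    "time_s": traj.times,
                    "x_mm": traj.x,
                    "y_mm": traj.y,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.4f")


def read_traces(path) -> List[CalciumTrace]:
    """Read a calcium CSV into one trace per neuron_id (single trace if absent)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    groups = (
        [(str(nid), g) for nid, g in df.groupby("neuron_id", sort=True)]
        if "neuron_id" in df.columns
        else [(path.stem, df)]
    )
    traces = []
    for nid, grp in groups:
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise SchemaError(f"{path}: non-monotone time for trace {nid!r}")
        fr = 1.0 / float(np.median(np.diff(times)))
        temp = (
            grp["temperature_C"].to_numpy(dtype=float)
            if "temperature_C" in grp.columns
            else None
        )
        traces.append(
            CalciumTrace(
                neuron_id=nid,
                times=times,
                fluorescence=grp["fluorescence_au"].to_numpy(dtype=float),
                temperature=temp,
                frame_rate=fr,
            )
        )
    return traces


def write_traces(traces: Sequence[CalciumTrace], path) -> None:
    rows = []
    for tr in traces:
        data = {
            "neuron_id": tr.neuron_id,
            "time_s": tr.times,
            "fluorescence_au": tr.fluorescence,
        }
        if tr.temperature is not None:
            data["temperature_C"] = tr.temperature
        rows.append(pd.DataFrame(data))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.4f")


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write a simulation's ground truth (turns or events) as its own CSV."""
    if truth.turns:
        df = pd.DataFrame(truth.turns)
    elif truth.events:
        df = pd.DataFrame(truth.events)
    else:
        df = pd.DataFrame()
    df.to_csv(path, index=False, float_format="%.6f")
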