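"""File outputs: trajectory containers, diagnostic tables, run metadata.

Trajectories go to a single ``.npz`` container (one array per snapshot and
field, plus coordinates) with a JSON metadata sidecar carrying the full
parameter set and grid so a run is self-describing and exactly repeatable.
Diagnostic tables are plain CSV with fixed column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import FrontTrace, ModeAmplitudeTrace, ProfileMetrics
from .solver import FIELD_NAMES, Trajectory

__all__ = [
    "save_trajectory",
    "load_trajectory_arrays",
    "write_front_trace",
    "write_mode_amplitude",
    "write_profile_metrics",
    "write_metadata",
]


def save_trajectory(traj: Trajectory, directory, write_csv: bool = False) -> Path:
    """Persist a trajectory as ``trajectory.npz`` (+ optional CSV tables)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {
        "times": traj.times,
        "x": traj.grid.x,
    }
    if traj.grid.y is not None:
        arrays["y"] = traj.grid.y
    for k, s in enumerate(traj.snapshots):
        for name, f in zip(FIELD_NAMES, s.fields()):
            arrays[f"snap{k:04d}_{name}"] = f
    path = directory / "trajectory.npz"
    np.savez(path, **arrays)
    write_metadata(traj.metadata, directory)
    if write_csv:
        for k, s in enumerate(traj.snapshots):
            df = _snapshot_table(traj, k)
            df.to_csv(directory / f"snapshot_{k:04d}.csv", index=False)
    return path


def _snapshot_table(traj: Trajectory, k: int) -> pd.DataFrame:
    s = traj.snapshots[k]
    if traj.grid.ndim == 1:
        return pd.DataFrame(
            {"x": traj.grid.x, "n": s.n, "m1": s.m1, "m2": s.m2, "g": s.g}
        )
    xx, yy = np.meshgrid(traj.grid.x, traj.grid.y, indexing="ij")
    return pd.DataFrame(
        {
            "x": xx.ravel(),
            "y": yy.ravel(),
            "n": s.n.ravel(),
            "m1": s.m1.ravel(),
            "m2": s.m2.ravel(),
            "g": s.g.ravel(),
        }
    )


def load_trajectory_arrays(path) -> dict[str, np.ndarray]:
    """Load a saved trajectory container back into a dict of arrays."""
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


def write_front_trace(trace: FrontTrace, directory) -> Path:
    path = Path(directory) / "front_trace.csv"
    pd.DataFrame({"t": trace.times, "x_f": trace.positions}).to_csv(path, index=False)
    return path


def write_mode_amplitude(trace: ModeAmplitudeTrace, directory) -> Path:
    path = Path(directory) / "mode_amplitude.csv"
    pd.DataFrame({"t": trace.times, "a_q": trace.amplitudes}).to_csv(path, index=False)
    return path


def write_profile_metrics(metrics: ProfileMetrics, directory) -> Path:
    path = Path(directory) / "profile_metrics.csv"
    pd.DataFrame(
        [
            {
                "classification": metrics.classification,
                "peak": metrics.peak,
                "peak_location": metrics.peak_location,
                "fwhm": metrics.fwhm if metrics.fwhm is not None else np.nan,
                "core_value": metrics.core_value,
                "core_nutrient": metrics.core_nutrient,
            }
        ]
    ).to_csv(path, index=False)
    return path


def write_metadata(metadata: dict, directory) -> Path:
    path = Path(directory) / "metadata.json"
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return path
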