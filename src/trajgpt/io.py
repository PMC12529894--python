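"""Plain-text trajectory formats.

Two dialects are supported, both bit-exact round-trippable:

* flat text: one integer state per line; a blank line separates source
  trajectories;
* CSV: columns ``traj_id,frame,state`` with a header, comma-separated,
  LF line endings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .systems import StateTrajectory

__all__ = ["read_states", "write_states", "read_states_csv", "write_states_csv"]


def write_states(traj: StateTrajectory, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for i, seg in enumerate(traj.segments()):
            if i:
                fh.write("\n")
            fh.writelines(f"{s}\n" for s in seg)


def read_states(path, frame_interval: float = 1.0) -> StateTrajectory:
    states: list[int] = []
    bounds: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if states and (not bounds or bounds[-1] != len(states)):
                    bounds.append(len(states))
                continue
            states.append(int(line))
    if not states:
        raise ValueError(f"no states in {path}")
    bounds = [b for b in bounds if 0 < b < len(states)]
    return StateTrajectory(np.asarray(states), np.asarray(bounds, dtype=int),
                           frame_interval=frame_interval)


def write_states_csv(traj: StateTrajectory, path) -> None:
    rows = []
    for tid, seg in enumerate(traj.segments()):
        rows.append(pd.DataFrame(
            {"traj_id": tid, "frame": np.arange(seg.size), "state": seg}
        ))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False,
                                              lineterminator="\n")


def read_states_csv(path, frame_interval: float = 1.0) -> StateTrajectory:
    df = pd.read_csv(path)
    expected = {"traj_id", "frame", "state"}
    if not expected.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(expected)}")
    df = df.sort_values(["traj_id", "frame"], kind="stable")
    ids = df["traj_id"].to_numpy()
    bounds = np.flatnonzero(ids[1:] != ids[:-1]) + 1
    return StateTrajectory(df["state"].to_numpy(dtype=np.int64), bounds,
                           frame_interval=frame_interval)
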