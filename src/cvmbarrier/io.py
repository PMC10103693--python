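"""Readers/writers for the shared plain-text formats.

Trajectories: CSV `sample_id,probe,particle_id,frame,x_um,y_um`
(0-based frames, micrometre coordinates, origin top-left).
Compositions: TSV, rows = samples, columns = taxa, relative abundances.
Cohort metadata: CSV with participant/sample/visit columns.
Videos: multi-page TIFF (see :mod:`cvmbarrier.simulate.video`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate.trajectories import Trajectory, TrajectorySet

TRAJECTORY_COLUMNS = ["sample_id", "probe", "particle_id", "frame",
                      "x_um", "y_um"]


def write_trajectories(path, df: pd.DataFrame) -> None:
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns {sorted(missing)}")
    df[TRAJECTORY_COLUMNS].to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns {sorted(missing)}")
    return df


def frame_to_trajectory_set(df: pd.DataFrame, dt: float) -> TrajectorySet:
    """Group a flat trajectory table (one sample, one probe) into objects."""
    trajectories = []
    for pid, grp in df.groupby("particle_id", sort=True):
        grp = grp.sort_values("frame")
        trajectories.append(Trajectory(
            particle_id=int(pid),
            frames=grp["frame"].to_numpy(dtype=np.int64),
            positions=grp[["x_um", "y_um"]].to_numpy(dtype=float),
            dt=dt))
    return TrajectorySet(trajectories=trajectories)


def write_composition_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_composition_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
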