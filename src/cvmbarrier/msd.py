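"""Time-averaged mean squared displacement (MSD) estimation.

The headline summary for mucus microrheology is the per-particle
time-averaged MSD at lag tau = 1 s, on the log10 scale (MSD in um^2):
trapped particles pile up at low log10 MSD, mobile particles at high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate.trajectories import Trajectory, TrajectorySet

logger = logging.getLogger(__name__)

__all__ = ["MSDRecord", "time_averaged_msd", "msd_at_one_second",
           "msd_table"]

#: MSD floor (um^2) so exactly-stationary particles get a finite log10.
MSD_FLOOR = 1e-6

#: Minimum displacement pairs at the target lag for a track to count.
MIN_PAIRS = 15


@dataclass
class MSDRecord:
    particle_id: int
    tau: float                  # s
    msd: float                  # um^2; NaN when span insufficient
    n_pairs: int
    log10_msd: float            # floored log10 of msd in um^2
    eligible: bool = True


def time_averaged_msd(traj: Trajectory, tau: float,
                      overlapping: bool = True,
                      floor: float = MSD_FLOOR) -> MSDRecord:
    """Time-averaged MSD of one trajectory at lag ``tau``.

    Averages |r(t+tau) - r(t)|^2 over all valid start frames
    (overlapping windows by default); frames missing from the track
    (gaps) contribute no pairs.  ``tau`` must be an integer multiple of
    the frame interval.  A trajectory spanning less than ``tau`` yields
    an ineligible record with msd = NaN.
    """
    lag_f = tau / traj.dt
    lag = int(round(lag_f))
    if abs(lag_f - lag) > 1e-9 or lag < 1:
        raise ValueError(
            f"tau={tau} is not a positive integer multiple of dt={traj.dt}")
    frames = traj.frames
    if frames[-1] - frames[0] < lag:
        return MSDRecord(traj.particle_id, tau, np.nan, 0, np.nan,
                         eligible=False)
    # match frames f with f+lag through a frame-index lookup
    idx = {int(f): i for i, f in enumerate(frames)}
    starts, ends = [], []
    first = int(frames[0])
    for i, f in enumerate(frames):
        f = int(f)
        if not overlapping and (f - first) % lag != 0:
            continue
        j = idx.get(f + lag)
        if j is not None:
            starts.append(i)
            ends.append(j)
    if not starts:
        return MSDRecord(traj.particle_id, tau, np.nan, 0, np.nan,
                         eligible=False)
    disp = traj.positions[ends] - traj.positions[starts]
    msd = float(np.mean(np.sum(disp ** 2, axis=1)))
    log10_msd = float(np.log10(max(msd, floor)))
    return MSDRecord(traj.particle_id, tau, msd, len(starts), log10_msd)


def msd_at_one_second(trajectories: TrajectorySet, tau: float = 1.0,
                      min_pairs: int = MIN_PAIRS,
                      floor: float = MSD_FLOOR) -> list[MSDRecord]:
    """Per-particle time-averaged MSD at tau (default 1 s).

    Returns one record per eligible particle (>= ``min_pairs``
    displacement pairs at the lag); ineligible particles are counted
    and logged, not returned.
    """
    if len(trajectories) == 0:
        logger.warning("msd_at_one_second called on empty trajectory set")
        return []
    records, n_ineligible = [], 0
    for traj in trajectories:
        rec = time_averaged_msd(traj, tau, floor=floor)
        if rec.eligible and rec.n_pairs >= min_pairs:
            records.append(rec)
        else:
            n_ineligible += 1
    if n_ineligible:
        logger.info("%d/%d particles ineligible at tau=%g s",
                    n_ineligible, len(trajectories), tau)
    return records


def msd_table(records: list[MSDRecord], sample_id: str = "sample",
              probe: str = "probe") -> pd.DataFrame:
    """Records as the shared per-particle MSD CSV schema."""
    return pd.DataFrame(
        [(sample_id, probe, r.particle_id, r.msd, r.log10_msd, r.n_pairs)
         for r in records],
        columns=["sample_id", "probe", "particle_id",
                 "msd_um2_tau1", "log10_msd", "n_pairs"])
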