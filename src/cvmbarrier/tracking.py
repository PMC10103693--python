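"""Particle localization and trajectory linking for video stacks.

A Crocker-Grier-style pipeline: per frame, a band-pass filter (small
Gaussian blur minus large-scale rolling background) suppresses noise
and uneven illumination, candidate spots are local maxima above an
intensity percentile, and positions are refined to sub-pixel precision
by an intensity-weighted centroid in a square window.  Frame-to-frame
linking solves a minimum-total-squared-displacement bipartite
assignment (Hungarian algorithm) gated by a maximum per-frame
displacement, with short-term memory for particles that blink out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .simulate.trajectories import OpticsConfig, Trajectory, TrajectorySet

logger = logging.getLogger(__name__)

__all__ = ["Spot", "DetectParams", "LinkParams",
           "detect_spots", "link_trajectories", "track_stack"]


@dataclass
class Spot:
    """One localized particle image in one frame (coordinates in um)."""

    frame: int
    x: float
    y: float
    mass: float          # integrated background-subtracted intensity
    sigma: float         # detection window scale, px
    ambiguous: bool = False


@dataclass(frozen=True)
class DetectParams:
    noise_sigma: float = 1.0       # px, small blur
    background_sigma: float = 8.0  # px, rolling background scale
    percentile: float = 99.5       # intensity threshold percentile
    window: int = 11               # px, odd refinement window
    min_mass: float = 0.0
    # discard candidates fainter than this fraction of the brightest
    # spot in the frame; suppresses shot-noise peaks in sparse fields
    min_mass_ratio: float = 0.1

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")


@dataclass(frozen=True)
class LinkParams:
    max_displacement: float = 0.5  # um per frame
    memory: int = 2                # frames a particle may vanish
    min_track_length: int = 30     # frames

    def __post_init__(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")


def _detect_frame(frame: np.ndarray, params: DetectParams,
                  pixel_size: float, frame_idx: int) -> list[Spot]:
    if frame.ndim != 2:
        raise ValueError(f"frames must be 2-D, got shape {frame.shape}")
    img = frame.astype(float)
    bandpassed = gaussian_filter(img, params.noise_sigma) \
        - gaussian_filter(img, params.background_sigma)
    if np.ptp(bandpassed) == 0:
        return []
    thresh = np.percentile(bandpassed, params.percentile)
    if thresh <= 0:
        thresh = np.finfo(float).eps
    half = params.window // 2
    peaks = peak_local_max(bandpassed, min_distance=2,
                           threshold_abs=thresh, exclude_border=half)
    if len(peaks) == 0:
        return []

    # maxima closer than the refinement window cannot be refined
    # independently: report once, flag ambiguous
    merged = np.zeros(len(peaks), dtype=bool)
    keep = np.ones(len(peaks), dtype=bool)
    for i in range(len(peaks)):
        if not keep[i]:
            continue
        d = np.max(np.abs(peaks - peaks[i]), axis=1)
        close = (d < params.window) & (np.arange(len(peaks)) != i)
        if np.any(close & keep):
            merged[i] = True
            keep[close] = False

    spots: list[Spot] = []
    for i in np.flatnonzero(keep):
        r, c = peaks[i]
        win = bandpassed[r - half:r + half + 1, c - half:c + half + 1]
        w = np.clip(win, 0, None)
        mass = float(w.sum())
        if mass <= params.min_mass or mass == 0:
            continue
        ys, xs = np.mgrid[-half:half + 1, -half:half + 1]
        dy = float((w * ys).sum() / mass)
        dx = float((w * xs).sum() / mass)
        spots.append(Spot(frame=frame_idx,
                          x=(c + dx) * pixel_size,
                          y=(r + dy) * pixel_size,
                          mass=mass, sigma=float(half),
                          ambiguous=bool(merged[i])))
    if spots and params.min_mass_ratio > 0:
        cap = max(s.mass for s in spots) * params.min_mass_ratio
        spots = [s for s in spots if s.mass >= cap]
    return spots


def detect_spots(stack: np.ndarray,
                 detect_params: DetectParams | None = None,
                 pixel_size: float = 0.025) -> list[Spot]:
    """Localize particles in every frame of a (T, H, W) stack.

    Empty or constant frames simply yield zero spots.  Coordinates are
    reported in micrometres (origin at the top-left pixel centre).
    """
    params = detect_params or DetectParams()
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"stack must be (T, H, W), got shape {stack.shape}")
    spots: list[Spot] = []
    for t in range(stack.shape[0]):
        spots.extend(_detect_frame(stack[t], params, pixel_size, t))
    return spots


@dataclass
class _Track:
    frames: list[int] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    ys: list[float] = field(default_factory=list)

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    @property
    def last_pos(self) -> tuple[float, float]:
        return self.xs[-1], self.ys[-1]


def link_trajectories(spots: list[Spot],
                      params: LinkParams | None = None,
                      dt: float = 1.0 / 15.0) -> TrajectorySet:
    """Link per-frame spots into trajectories.

    Per frame pair, a globally optimal assignment minimizes total
    squared displacement subject to ``max_displacement`` per elapsed
    frame (Hungarian algorithm with virtual no-match entries).  Spots
    flagged ambiguous are excluded.  Tracks shorter than
    ``min_track_length`` observations are discarded.
    """
    params = params or LinkParams()
    usable = sorted((s for s in spots if not s.ambiguous),
                    key=lambda s: s.frame)
    by_frame: dict[int, list[Spot]] = {}
    for s in usable:
        by_frame.setdefault(s.frame, []).append(s)

    active: list[_Track] = []
    finished: list[_Track] = []

    for frame in sorted(by_frame):
        frame_spots = by_frame[frame]
        # retire tracks whose gap exceeds memory
        still_active = []
        for tr in active:
            if frame - tr.last_frame > params.memory + 1:
                finished.append(tr)
            else:
                still_active.append(tr)
        active = still_active

        n_t, n_s = len(active), len(frame_spots)
        assigned_spot = [False] * n_s
        if n_t and n_s:
            # squared-distance cost, gated; pad square so every track/spot
            # may go unmatched at the gate cost
            big = np.inf
            gate2 = np.empty(n_t)
            cost = np.full((n_t + n_s, n_t + n_s), 0.0)
            d2 = np.full((n_t, n_s), big)
            for i, tr in enumerate(active):
                gap = frame - tr.last_frame
                gate2[i] = (params.max_displacement * gap) ** 2
                tx, ty = tr.last_pos
                for j, s in enumerate(frame_spots):
                    dd = (s.x - tx) ** 2 + (s.y - ty) ** 2
                    if dd <= gate2[i]:
                        d2[i, j] = dd
            # replace inf by a large finite cost so assignment is feasible
            finite_cap = (np.nanmax(gate2) + 1.0) * 10
            cost[:n_t, :n_s] = np.where(np.isfinite(d2), d2, finite_cap * 100)
            cost[:n_t, n_s:] = finite_cap       # track unmatched
            cost[n_t:, :n_s] = finite_cap       # spot starts new track
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if i < n_t and j < n_s and np.isfinite(d2[i, j]):
                    tr, s = active[i], frame_spots[j]
                    tr.frames.append(frame)
                    tr.xs.append(s.x)
                    tr.ys.append(s.y)
                    assigned_spot[j] = True
        for j, s in enumerate(frame_spots):
            if not assigned_spot[j]:
                active.append(_Track(frames=[frame], xs=[s.x], ys=[s.y]))

    finished.extend(active)
    trajectories = []
    pid = 0
    for tr in finished:
        if len(tr.frames) >= params.min_track_length:
            trajectories.append(Trajectory(
                particle_id=pid,
                frames=np.asarray(tr.frames),
                positions=np.column_stack([tr.xs, tr.ys]),
                dt=dt))
            pid += 1
    logger.info("linked %d spots into %d tracks (%d discarded short)",
                len(usable), len(trajectories), len(finished) - len(trajectories))
    return TrajectorySet(trajectories=trajectories)


def track_stack(stack: np.ndarray,
                optics: OpticsConfig | None = None,
                detect_params: DetectParams | None = None,
                link_params: LinkParams | None = None) -> TrajectorySet:
    """Detect and link a full stack in one call."""
    optics = optics or OpticsConfig()
    spots = detect_spots(stack, detect_params, pixel_size=optics.pixel_size)
    return link_trajectories(spots, link_params, dt=optics.dt)


def trajectories_to_frame(trajset: TrajectorySet, sample_id: str = "sample",
                          probe: str = "probe") -> pd.DataFrame:
    """Flatten a TrajectorySet into the shared trajectory CSV schema."""
    rows = []
    for traj in trajset:
        for f, (x, y) in zip(traj.frames, traj.positions):
            rows.append((sample_id, probe, traj.particle_id, int(f), x, y))
    return pd.DataFrame(rows, columns=[
        "sample_id", "probe", "particle_id", "frame", "x_um", "y_um"])
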