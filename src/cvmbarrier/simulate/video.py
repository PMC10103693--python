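"""Render trajectory sets into synthetic fluorescence video stacks.

Each frame is a constant background plus one symmetric Gaussian spot per
particle, corrupted with Poisson shot noise, emulating EM-CCD
acquisition of fluorescent nanoparticles.  Frames are unsigned 16-bit;
stacks are written as multi-page TIFF, one page per frame.
"""

from __future__ import annotations

import numpy as np

from .trajectories import OpticsConfig, TrajectorySet

__all__ = ["render_video", "write_tiff", "read_tiff"]


def _paint_spot(frame: np.ndarray, x_px: float, y_px: float,
                amplitude: float, sigma: float) -> None:
    """Add a Gaussian spot in-place, restricted to a +/-4 sigma window."""
    h, w = frame.shape
    r = max(int(np.ceil(4 * sigma)), 2)
    x0, x1 = int(np.floor(x_px)) - r, int(np.floor(x_px)) + r + 1
    y0, y1 = int(np.floor(y_px)) - r, int(np.floor(y_px)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    gx = np.exp(-0.5 * ((xs - x_px) / sigma) ** 2)
    gy = np.exp(-0.5 * ((ys - y_px) / sigma) ** 2)
    frame[y0c:y1c, x0c:x1c] += amplitude * np.outer(gy, gx)


def render_video(
    trajectories: TrajectorySet,
    optics: OpticsConfig | None = None,
    seed: int | np.random.Generator | None = None,
    out_of_field: str = "reject",
    shot_noise: bool = True,
) -> np.ndarray:
    """Render a trajectory set into a (n_frames, H, W) uint16 stack.

    ``out_of_field`` controls particles leaving the field of view:
    ``"reject"`` (default) raises at render time, ``"clip"`` silently
    renders only the in-field part of each spot.
    """
    optics = optics or OpticsConfig()
    if out_of_field not in ("reject", "clip"):
        raise ValueError(f"out_of_field must be 'reject' or 'clip', got {out_of_field!r}")
    rng = np.random.default_rng(seed)
    h, w = optics.image_shape
    n_frames = optics.n_frames
    px = optics.pixel_size

    if out_of_field == "reject":
        for traj in trajectories:
            xy_px = traj.positions / px
            if (np.any(xy_px < 0)
                    or np.any(xy_px[:, 0] >= w) or np.any(xy_px[:, 1] >= h)):
                raise ValueError(
                    f"particle {traj.particle_id} leaves the field of view; "
                    "use out_of_field='clip' to render anyway")

    stack = np.full((n_frames, h, w), float(optics.background))
    for traj in trajectories:
        for frame_idx, (x_um, y_um) in zip(traj.frames, traj.positions):
            if frame_idx >= n_frames:
                continue
            _paint_spot(stack[frame_idx], x_um / px, y_um / px,
                        optics.photon_scale, optics.psf_sigma)
    if shot_noise:
        stack = rng.poisson(stack).astype(float)
    return np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)


def write_tiff(path, stack: np.ndarray) -> None:
    import tifffile
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_tiff(path) -> np.ndarray:
    import tifffile
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr
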