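"""Displacement compensation by Lucas–Kanade point tracking.

Small subject motion moves the skin region under any fixed pixel, so a
fixed-coordinate trace mixes skin and background and buries the pulse.
This stage estimates the apparent motion of chosen skin points between
adjacent frames under the three classic LK assumptions — brightness
constancy, small motion, and locally constant flow over an m×m window —
and samples the channel traces along the tracked trajectories instead of
at fixed coordinates.

For a window W around a point, with spatial gradients I_x, I_y of the
previous frame and temporal difference I_t, the flow (u, v) solves the
2×2 normal equations

    [ΣI_x²   ΣI_xI_y] [u]   [−ΣI_xI_t]
    [ΣI_xI_y  ΣI_y² ] [v] = [−ΣI_yI_t]

A window with a near-singular normal matrix (the aperture problem — e.g.
a uniform or one-dimensional texture) has no recoverable flow; such
frames are flagged invalid. The single-step solution is accurate only for
sub-pixel steps, so by default the solve is refined iteratively by warping
the next frame onto the current estimate (≤ ``max_iter`` rounds, stopping
when the update drops below 0.01 px); ``max_iter=1`` reproduces the
single-step estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateFlowError, TrackingError

DEFAULT_WINDOW_M = 15
DEFAULT_MIN_EIG_SCALE = 1e-4  # threshold = scale * window pixel count, 0-255 gradients


@dataclass
class FlowEstimate:
    """A per-point flow vector with the conditioning of its normal matrix."""

    u: float
    v: float
    conditioning: float  # smallest eigenvalue of the 2x2 normal matrix


@dataclass
class Trajectory:
    """Sub-pixel positions of one tracked point across all frames."""

    point_id: int
    positions: np.ndarray  # (N, 2) as (x, y)
    valid: np.ndarray  # (N,) bool

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def displacements(self) -> np.ndarray:
        """Per-frame displacement relative to the seed position."""
        return self.positions - self.positions[0]


def _window_grid(x: float, y: float, m: int) -> tuple[np.ndarray, np.ndarray]:
    half = m // 2
    off = np.arange(-half, half + 1, dtype=np.float64)
    gy, gx = np.meshgrid(y + off, x + off, indexing="ij")
    return gy, gx


class _CropSampler:
    """Cubic-spline sampler over a small crop around a point.

    Pre-filters only the crop (not the whole frame), which keeps repeated
    window sampling during iterative refinement cheap.
    """

    def __init__(self, img: np.ndarray, x: float, y: float, half: int, pad: int = 6):
        h, w = img.shape
        self.y0 = max(0, int(np.floor(y)) - half - pad)
        self.x0 = max(0, int(np.floor(x)) - half - pad)
        y1 = min(h, int(np.ceil(y)) + half + pad + 1)
        x1 = min(w, int(np.ceil(x)) + half + pad + 1)
        self.coeffs = ndimage.spline_filter(
            np.ascontiguousarray(img[self.y0:y1, self.x0:x1]), order=3, mode="nearest"
        )

    def __call__(self, gy: np.ndarray, gx: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            self.coeffs, [gy - self.y0, gx - self.x0],
            order=3, mode="nearest", prefilter=False,
        )


def lk_flow(
    prev: np.ndarray,
    next_: np.ndarray,
    point: tuple[float, float],
    window_m: int = DEFAULT_WINDOW_M,
    max_iter: int = 5,
    tol: float = 0.01,
    min_eig_scale: float = DEFAULT_MIN_EIG_SCALE,
    gradients: tuple[np.ndarray, np.ndarray] | None = None,
    init: tuple[float, float] = (0.0, 0.0),
) -> FlowEstimate:
    """Estimate the flow (u, v) of ``point`` (x, y) from ``prev`` to ``next_``.

    Gradients are central differences on ``prev`` (pass ``gradients``
    = (I_y, I_x) to reuse precomputed full-frame arrays). ``init`` seeds
    the iterative refinement with a known approximate displacement, which
    lets the solver refine a larger total motion while each linearized
    step stays sub-pixel. Raises :class:`DegenerateFlowError` when the
    smallest eigenvalue of the normal matrix falls below
    ``min_eig_scale``·m².
    """
    if window_m % 2 != 1 or window_m < 3:
        raise ConfigurationError(f"window_m must be odd and >= 3, got {window_m}")
    prev = np.asarray(prev, dtype=np.float64)
    next_ = np.asarray(next_, dtype=np.float64)
    x, y = float(point[0]), float(point[1])
    h, w = prev.shape
    margin = window_m // 2 + 1
    if not (margin <= x <= w - 1 - margin and margin <= y <= h - 1 - margin):
        raise ConfigurationError(
            f"point ({x:.1f}, {y:.1f}) too close to the border for window {window_m}"
        )
    if gradients is None:
        iy_img, ix_img = np.gradient(prev)
    else:
        iy_img, ix_img = gradients

    half = window_m // 2
    gy, gx = _window_grid(x, y, window_m)
    ix = _CropSampler(ix_img, x, y, half)(gy, gx).ravel()
    iy = _CropSampler(iy_img, x, y, half)(gy, gx).ravel()
    prev_win = _CropSampler(prev, x, y, half)(gy, gx).ravel()
    pad = 6 + int(np.ceil(max(abs(init[0]), abs(init[1]))))
    next_sampler = _CropSampler(next_, x + init[0], y + init[1], half, pad=pad)

    gxx = float(ix @ ix)
    gxy = float(ix @ iy)
    gyy = float(iy @ iy)
    trace_half = 0.5 * (gxx + gyy)
    det = gxx * gyy - gxy * gxy
    lam_min = trace_half - np.sqrt(max(trace_half**2 - det, 0.0))
    threshold = min_eig_scale * window_m**2
    if lam_min < threshold:
        raise DegenerateFlowError(
            f"aperture problem at ({x:.1f}, {y:.1f}): lambda_min={lam_min:.3g} < {threshold:.3g}"
        )

    u, v = float(init[0]), float(init[1])
    for _ in range(max(1, max_iter)):
        warped = next_sampler(gy + v, gx + u).ravel()
        it = warped - prev_win
        bx = -float(ix @ it)
        by = -float(iy @ it)
        du = (gyy * bx - gxy * by) / det
        dv = (gxx * by - gxy * bx) / det
        u += du
        v += dv
        if du * du + dv * dv < tol * tol:
            break
    return FlowEstimate(u=u, v=v, conditioning=lam_min)


def min_eig_map(gray: np.ndarray, window_m: int = DEFAULT_WINDOW_M) -> np.ndarray:
    """Smallest-eigenvalue map of the LK normal matrix (corner strength)."""
    gray = np.asarray(gray, dtype=np.float64)
    iy, ix = np.gradient(gray)
    size = (window_m, window_m)
    gxx = ndimage.uniform_filter(ix * ix, size=size, mode="nearest") * window_m**2
    gxy = ndimage.uniform_filter(ix * iy, size=size, mode="nearest") * window_m**2
    gyy = ndimage.uniform_filter(iy * iy, size=size, mode="nearest") * window_m**2
    tr = 0.5 * (gxx + gyy)
    det = gxx * gyy - gxy * gxy
    return tr - np.sqrt(np.maximum(tr * tr - det, 0.0))


def select_seeds(
    gray: np.ndarray,
    mask: np.ndarray,
    n_seeds: int = 3,
    window_m: int = DEFAULT_WINDOW_M,
    min_spacing: int | None = None,
) -> np.ndarray:
    """Pick ``n_seeds`` well-conditioned, well-separated points inside ``mask``.

    Deterministic: points are chosen greedily by descending corner strength
    with a minimum mutual spacing. Returns (n, 2) float (x, y).
    """
    h, w = gray.shape
    margin = window_m // 2 + 2
    score = min_eig_map(gray, window_m)
    eroded = ndimage.binary_erosion(mask, iterations=margin) if mask.any() else mask
    allowed = eroded.copy()
    allowed[:margin] = allowed[-margin:] = False
    allowed[:, :margin] = allowed[:, -margin:] = False
    if not allowed.any():
        raise TrackingError("no valid seed locations inside the skin mask")
    score = np.where(allowed, score, -np.inf)
    if min_spacing is None:
        min_spacing = max(2 * window_m, 10)
    order = np.argsort(score.ravel())[::-1]
    seeds: list[tuple[float, float]] = []
    for flat in order:
        if not np.isfinite(score.ravel()[flat]):
            break
        yy, xx = divmod(int(flat), w)
        if all((xx - sx) ** 2 + (yy - sy) ** 2 >= min_spacing**2 for sx, sy in seeds):
            seeds.append((float(xx), float(yy)))
            if len(seeds) == n_seeds:
                break
    if not seeds:
        raise TrackingError("could not find any textured seed points")
    return np.asarray(seeds, dtype=np.float64)


def track_points(
    frames_gray: np.ndarray,
    seeds: np.ndarray,
    window_m: int = DEFAULT_WINDOW_M,
    max_disp: float = 2.0,
    max_iter: int = 5,
    min_eig_scale: float = DEFAULT_MIN_EIG_SCALE,
    template_refine: bool = True,
) -> list[Trajectory]:
    """Track seed points through an (N, H, W) gray stack frame-to-frame.

    Each step integrates :func:`lk_flow` between adjacent frames. With
    ``template_refine`` (default) the integrated position is then
    re-anchored against the first frame's window, using the integrated
    displacement as initialization: per-step errors no longer accumulate
    as a random walk, while each linearized solve still only handles a
    sub-pixel residual. A trajectory is truncated (marked invalid from
    that frame on) when the window becomes degenerate, the step exceeds
    ``max_disp`` px (the small-motion regime) or the point approaches the
    border. Raises :class:`TrackingError` if every trajectory dies before
    50% of frames.
    """
    frames_gray = np.asarray(frames_gray, dtype=np.float64)
    n, h, w = frames_gray.shape
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.float64))
    margin = window_m // 2 + 1

    n_pts = len(seeds)
    pos = np.tile(seeds[:, None, :], (1, n, 1))  # (n_pts, n, 2)
    valid = np.ones((n_pts, n), dtype=bool)
    alive = np.ones(n_pts, dtype=bool)
    grad0 = np.gradient(frames_gray[0]) if template_refine else None
    for i in range(n - 1):
        if not alive.any():
            valid[:, i + 1 :] = False
            break
        gradients = np.gradient(frames_gray[i])
        for p in range(n_pts):
            if not alive[p]:
                valid[p, i + 1] = False
                continue
            try:
                est = lk_flow(
                    frames_gray[i],
                    frames_gray[i + 1],
                    pos[p, i],
                    window_m=window_m,
                    max_iter=max_iter,
                    min_eig_scale=min_eig_scale,
                    gradients=gradients,
                )
                step_ok = np.hypot(est.u, est.v) <= max_disp
            except (DegenerateFlowError, ConfigurationError):
                step_ok = False
            if not step_ok:
                alive[p] = False
                valid[p, i + 1] = False
                pos[p, i + 1 :] = pos[p, i]
                continue
            new = pos[p, i] + (est.u, est.v)
            if template_refine:
                try:
                    ref = lk_flow(
                        frames_gray[0],
                        frames_gray[i + 1],
                        seeds[p],
                        window_m=window_m,
                        max_iter=max_iter,
                        min_eig_scale=min_eig_scale,
                        gradients=grad0,
                        init=tuple(new - seeds[p]),
                    )
                    refined = seeds[p] + (ref.u, ref.v)
                    # accept the re-anchored position only if it stays
                    # consistent with the integrated one
                    if np.hypot(*(refined - new)) <= 1.0:
                        new = refined
                except (DegenerateFlowError, ConfigurationError):
                    pass
            if not (margin <= new[0] <= w - 1 - margin and margin <= new[1] <= h - 1 - margin):
                alive[p] = False
                valid[p, i + 1] = False
                pos[p, i + 1 :] = pos[p, i]
                continue
            pos[p, i + 1 :] = new
    trajectories = [
        Trajectory(point_id=p, positions=pos[p], valid=valid[p]) for p in range(n_pts)
    ]

    if all(t.n_valid < n // 2 for t in trajectories):
        raise TrackingError("all trajectories became invalid before 50% of frames")
    return trajectories


def interpolate_positions(traj: Trajectory) -> np.ndarray:
    """Positions with invalid frames filled by linear interpolation in time."""
    pos = traj.positions.copy()
    idx = np.arange(len(pos))
    good = traj.valid
    if good.all():
        return pos
    for c in range(2):
        pos[:, c] = np.interp(idx, idx[good], pos[good, c])
    return pos


def sample_traces(frames: np.ndarray, trajectories: list[Trajectory], fps: float):
    """Bilinearly sample (N, H, W, 3) frames along each trajectory.

    Returns one :class:`~ippg.spatial.ChannelTraces` per trajectory, with
    invalid frames filled by linearly interpolated positions. Trajectories
    valid on fewer than half the frames are rejected upstream.
    """
    from .spatial import ChannelTraces  # local import to avoid a cycle

    frames = np.asarray(frames, dtype=np.float64)
    n = frames.shape[0]
    out = []
    for traj in trajectories:
        pos = interpolate_positions(traj)
        vals = np.empty((n, 3))
        for i in range(n):
            coords = [[pos[i, 1]], [pos[i, 0]]]
            for c in range(3):
                vals[i, c] = ndimage.map_coordinates(
                    frames[i, :, :, c], coords, order=1, mode="nearest"
                )[0]
        out.append(ChannelTraces(vals[:, 0], vals[:, 1], vals[:, 2], fps))
    return out


def median_displacement(trajectories: list[Trajectory]) -> np.ndarray:
    """Per-frame median displacement (dx, dy) across valid trajectories."""
    n = len(trajectories[0].positions)
    disp = np.zeros((n, 2))
    stack = np.stack([interpolate_positions(t) - t.positions[0] for t in trajectories])
    disp = np.median(stack, axis=0)
    return disp


def roi_traces_tracked(frames: np.ndarray, mask: np.ndarray, displacement: np.ndarray, fps: float):
    """ROI-mean traces over a mask re-centered by a per-frame displacement.

    The reference-frame mask coordinates are shifted by ``displacement``
    (frame-relative (dx, dy)) and sampled bilinearly, so the ROI follows
    the subject instead of staying glued to fixed pixels.
    """
    from .spatial import ChannelTraces

    frames = np.asarray(frames, dtype=np.float64)
    ys, xs = np.nonzero(mask)
    n = frames.shape[0]
    vals = np.empty((n, 3))
    for i in range(n):
        dx, dy = displacement[i]
        if dx == 0.0 and dy == 0.0:
            vals[i] = frames[i][mask].mean(axis=0)
            continue
        coords = [ys + dy, xs + dx]
        for c in range(3):
            vals[i, c] = ndimage.map_coordinates(
                frames[i, :, :, c], coords, order=1, mode="nearest"
            ).mean()
    return ChannelTraces(vals[:, 0], vals[:, 1], vals[:, 2], fps)
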