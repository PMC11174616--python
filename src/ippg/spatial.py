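"""Spatial processing: Gaussian smoothing, skin-color detection, channel traces.

The first pipeline stage denoises every frame with a 5×5 Gaussian kernel
(σ = 1 px), gates skin pixels with joint thresholds on hue (HSV) and the
Cb/Cr chroma planes (YCbCr), and reduces each frame to R/G/B time series
over the detected skin region.

Conventions
-----------
* Hue is on the half-degree scale H ∈ [0, 180), the common 8-bit video
  convention; the skin band 1 ≤ H ≤ 23 covers hues of roughly 2°–46°.
* Cb/Cr are full-range BT.601 with the usual +128 offset, so the skin box
  77 ≤ Cb ≤ 127, 133 ≤ Cr ≤ 173 applies directly to 8-bit RGB input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv

from .errors import ConfigurationError, SignalQualityError


# ---------------------------------------------------------------------------
# Gaussian smoothing
# ---------------------------------------------------------------------------

@dataclass
class SmoothingKernel:
    """A small separable-Gaussian convolution kernel, renormalized to sum 1.

    ``raw_sum`` preserves the sum of the sampled (unnormalized) Gaussian;
    the sampled 5×5 σ=1 kernel sums to ≈0.982, so renormalization keeps
    constant images constant.
    """

    weights: np.ndarray
    sigma: float
    raw_sum: float

    @property
    def size(self) -> int:
        return self.weights.shape[0]


def gaussian_kernel(sigma: float = 1.0, size: int = 5) -> SmoothingKernel:
    """Sample the 2-D Gaussian on a ``size``×``size`` grid and normalize.

    With the defaults (σ = 1, 5×5) the sampled weights round to the classic
    matrix with center 0.159 and corner 0.003.
    """
    if size % 2 != 1 or size < 1:
        raise ConfigurationError(f"kernel size must be odd and positive, got {size}")
    if sigma <= 0:
        raise ConfigurationError(f"sigma must be positive, got {sigma}")
    half = size // 2
    x = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(x, x)
    raw = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
    raw_sum = float(raw.sum())
    return SmoothingKernel(weights=raw / raw_sum, sigma=sigma, raw_sum=raw_sum)


def gaussian_smooth(frame: np.ndarray, kernel: SmoothingKernel) -> np.ndarray:
    """Convolve each channel with the kernel; borders are edge-replicated."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim == 2:
        return ndimage.correlate(frame, kernel.weights, mode="nearest")
    out = np.empty_like(frame)
    for c in range(frame.shape[-1]):
        out[..., c] = ndimage.correlate(frame[..., c], kernel.weights, mode="nearest")
    return out


def smooth_sequence(frames: np.ndarray, kernel: SmoothingKernel) -> np.ndarray:
    """Smooth an (N, H, W, 3) stack; returns float32 to bound memory.

    The sampled-Gaussian kernel is an outer product of its 1-D profile, so
    the 2-D convolution is applied as two 1-D passes.
    """
    frames = np.asarray(frames, dtype=np.float32)
    # the normalized kernel is outer(p, p) with p = sqrt(diag(kernel))
    w1 = np.sqrt(np.diag(kernel.weights))
    w1 = (w1 / w1.sum()).astype(np.float32)
    out = np.empty_like(frames)
    for c in range(frames.shape[-1]):
        tmp = ndimage.correlate1d(frames[..., c], w1, axis=1, mode="nearest")
        out[..., c] = ndimage.correlate1d(tmp, w1, axis=2, mode="nearest")
    return out


# ---------------------------------------------------------------------------
# Skin detection
# ---------------------------------------------------------------------------

@dataclass
class SkinBounds:
    """Inclusive skin-gate box in (H half-degrees, Cb, Cr)."""

    h_min: float = 1.0
    h_max: float = 23.0
    cb_min: float = 77.0
    cb_max: float = 127.0
    cr_min: float = 133.0
    cr_max: float = 173.0


@dataclass
class SkinMask:
    """Per-frame boolean skin gate with its pixel coverage fraction."""

    mask: np.ndarray
    coverage: float = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.coverage = float(self.mask.mean()) if self.mask.size else 0.0


def hue_halfdeg(frame: np.ndarray) -> np.ndarray:
    """Hue of an 8-bit-scale RGB frame on the half-degree scale [0, 180)."""
    rgb = np.asarray(frame, dtype=np.float64) / 255.0
    return rgb2hsv(rgb)[..., 0] * 180.0


def cb_cr(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full-range BT.601 Cb, Cr planes of an 8-bit-scale RGB frame."""
    f = np.asarray(frame, dtype=np.float64)
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 + 0.564 * (b - y)
    cr = 128.0 + 0.713 * (r - y)
    return cb, cr


def skin_gate(
    h: np.ndarray, cb: np.ndarray, cr: np.ndarray, bounds: SkinBounds | None = None
) -> np.ndarray:
    """The pure per-pixel skin predicate on (H, Cb, Cr) values, bounds inclusive."""
    b = bounds or SkinBounds()
    return (
        (h >= b.h_min) & (h <= b.h_max)
        & (cb >= b.cb_min) & (cb <= b.cb_max)
        & (cr >= b.cr_min) & (cr <= b.cr_max)
    )


def detect_skin(frame: np.ndarray, bounds: SkinBounds | None = None) -> SkinMask:
    """Gate skin pixels of an RGB frame by the joint H/Cb/Cr box."""
    h = hue_halfdeg(frame)
    cb, cr = cb_cr(frame)
    return SkinMask(skin_gate(h, cb, cr, bounds))


def clean_mask(mask: SkinMask, keep_largest: bool = True) -> SkinMask:
    """Morphological cleanup: 3×3 open/close, optionally keep the largest blob.

    The raw color gate leaves salt-and-pepper holes; opening then closing
    with a 3×3 structuring element removes them, and restricting to the
    largest connected component drops stray background matches.
    """
    m = mask.mask
    selem = np.ones((3, 3), dtype=bool)
    m = ndimage.binary_opening(m, structure=selem)
    m = ndimage.binary_closing(m, structure=selem)
    if keep_largest and m.any():
        labels, n = ndimage.label(m)
        if n > 1:
            sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
            m = labels == (1 + int(np.argmax(sizes)))
    return SkinMask(m)


# ---------------------------------------------------------------------------
# Channel decomposition
# ---------------------------------------------------------------------------

@dataclass
class ChannelTraces:
    """Time series of R, G, B values for an ROI mean or a tracked point."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    fps: float

    @property
    def n_samples(self) -> int:
        return len(self.r)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fps

    def stacked(self) -> np.ndarray:
        return np.stack([self.r, self.g, self.b])


def decompose_channels(
    frames: np.ndarray,
    masks: list[SkinMask] | SkinMask,
    fps: float,
    mode: str = "roi-mean",
    points: np.ndarray | None = None,
    max_gap_fraction: float = 0.10,
) -> ChannelTraces:
    """Reduce an (N, H, W, 3) stack to R/G/B time series.

    ``roi-mean`` averages over the skin mask per frame (a single mask is
    broadcast to all frames). Frames whose mask is empty are gap-filled by
    linear interpolation; more than ``max_gap_fraction`` gap frames is a
    hard error. ``per-pixel`` samples fixed integer pixel coordinates
    (``points``, shape (k, 2) as (x, y)) and averages them.
    """
    frames = np.asarray(frames)
    n = frames.shape[0]
    if mode == "per-pixel":
        if points is None:
            raise ConfigurationError("per-pixel mode requires points")
        pts = np.asarray(points, dtype=int)
        vals = frames[:, pts[:, 1], pts[:, 0], :].mean(axis=1)
        return ChannelTraces(vals[:, 0], vals[:, 1], vals[:, 2], fps)
    if mode != "roi-mean":
        raise ConfigurationError(f"unknown mode {mode!r}")

    if isinstance(masks, SkinMask):
        mask_list = [masks] * n
    else:
        mask_list = list(masks)
        if len(mask_list) != n:
            raise ConfigurationError("one mask per frame required")
    out = np.full((n, 3), np.nan)
    gaps = 0
    for i, sm in enumerate(mask_list):
        m = sm.mask
        if not m.any():
            gaps += 1
            continue
        out[i] = frames[i][m].mean(axis=0)
    if gaps > max_gap_fraction * n:
        raise SignalQualityError(
            f"{gaps}/{n} frames have an empty skin mask (> {max_gap_fraction:.0%})"
        )
    if gaps:
        idx = np.arange(n)
        good = ~np.isnan(out[:, 0])
        for c in range(3):
            out[:, c] = np.interp(idx, idx[good], out[good, c])
    return ChannelTraces(out[:, 0], out[:, 1], out[:, 2], fps)
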