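"""Ambient-light drift compensation.

The compensator assumes that the mean intensity of a fixed-size window
around any pixel is constant over time; any change in that windowed mean is
attributed to ambient light and removed. Concretely, a 2a×2b box mean
g_n(i, j) is computed per frame and per channel, and every pixel is
corrected by the drift of its windowed mean relative to the first frame:

    I*_n(i, j) = I'_n(i, j) − (g_n(i, j) − g_1(i, j))

The R, G and B channels are compensated independently. The subtraction
cancels the drift; ``sign="add"`` applies the difference additively
instead, which doubles the drift and is kept only for comparison.

Because the pulse also moves the windowed mean wherever the window lies
entirely on pulsing skin, compensation attenuates (but does not remove) a
spatially uniform pulse; the window should therefore be no smaller than the
default 32×32 so that a useful fraction of the pulse survives near the ROI
boundary. See the methods note for the quantitative trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError

DEFAULT_WINDOW_HALF = 16  # a = b = 16 -> 32x32 window


def local_mean(channel: np.ndarray, a: int = DEFAULT_WINDOW_HALF, b: int | None = None) -> np.ndarray:
    """Box-filter mean over an exactly 2a×2b-pixel window, edge-replicated.

    ``a`` is the horizontal half-width, ``b`` the vertical half-width
    (default: equal). The window at pixel (i, j) spans rows
    [i−b, i+b−1] and columns [j−a, j+a−1], so the divisor equals the
    window area 2a·2b and a constant image is preserved exactly.
    """
    if b is None:
        b = a
    channel = np.asarray(channel, dtype=np.float64)
    h, w = channel.shape[-2:]
    if 2 * a > w or 2 * b > h or a < 1 or b < 1:
        raise ConfigurationError(
            f"window {2*a}x{2*b} invalid for a {h}x{w} frame"
        )
    return ndimage.uniform_filter(channel, size=(2 * b, 2 * a), mode="nearest")


@dataclass
class CompensatedSequence:
    """Drift-compensated frames (float), referenced to the first frame."""

    frames: np.ndarray
    window_half: tuple[int, int]
    sign: str
    reference_frame_index: int = 0


def compensate_light(
    frames: np.ndarray,
    a: int = DEFAULT_WINDOW_HALF,
    b: int | None = None,
    sign: str = "subtract",
) -> CompensatedSequence:
    """Compensate per-channel intensity drift against the first frame.

    ``frames`` is an (N, H, W, C) stack (typically the smoothed frames);
    each channel is treated independently. The first frame is returned
    unchanged. ``sign="subtract"`` subtracts the windowed-mean drift
    (cancelling it); ``sign="add"`` adds it.
    """
    if b is None:
        b = a
    if sign not in ("subtract", "add"):
        raise ConfigurationError(f"sign must be 'subtract' or 'add', got {sign!r}")
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 3:
        frames = frames[..., None]
        squeeze = True
    else:
        squeeze = False
    n, h, w = frames.shape[:3]
    if n < 2:
        raise ConfigurationError("light compensation needs at least 2 frames")
    if 2 * a > w or 2 * b > h or a < 1 or b < 1:
        raise ConfigurationError(f"window {2*a}x{2*b} invalid for a {h}x{w} frame")

    out = np.empty_like(frames)
    for c in range(frames.shape[-1]):
        chan = frames[..., c]
        # box mean per frame: filter only over the spatial axes
        g = ndimage.uniform_filter(chan, size=(1, 2 * b, 2 * a), mode="nearest")
        drift = g - g[0]
        if sign == "subtract":
            out[..., c] = chan - drift
        else:
            out[..., c] = chan + drift
        out[0, ..., c] = chan[0]
    if squeeze:
        out = out[..., 0]
    return CompensatedSequence(out, window_half=(a, b), sign=sign)
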