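"""Synthetic face-video generator with exact ground truth.

Frames follow the dichromatic skin-reflection model: the value of channel
C ∈ {R, G, B} of a skin pixel in frame k is

    C_k = I_C · (ρ_Cdc + ρ_C·p(t_k) + S(t_k))

where I_C·ρ_Cdc is the static skin color (with ρ_Rdc > ρ_Gdc > ρ_Bdc),
ρ_C is the per-channel pulsatile modulation depth, p(t) the pulse
waveform at the heart frequency, and S(t) a specular component shared
equally by all channels. On top of the model the generator adds a global
additive ambient-light drift, translational subject motion (rendered at
sub-pixel resolution), and per-pixel Gaussian sensor noise, then
quantizes to 8 bits.

The scene is an elliptical skin patch — whose color passes the pipeline's
H/Cb/Cr skin gate — over a neutral gray textured background that fails
the gate. A gentle multiplicative texture rides on the patch so that
optical-flow tracking has gradients to lock onto; it moves rigidly with
the patch. Every random quantity flows from the scenario's single seed,
so a scenario generates bit-identical output on every run.

The generator emulates the study axes (pulse frequency, drift profile,
sway amplitude, light level, subject distance) but not photorealistic
faces, physiologic waveform detail beyond an optional fast-systole shape,
or camera gain/exposure dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .spatial import detect_skin
from .video_io import FrameSequence

DEFAULT_BASE_COLOR = (200.0, 140.0, 110.0)
DEFAULT_PULSE_AMP = (0.002, 0.004, 0.002)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    hr_hz: float
    bpm_true: float
    pulse_trace: np.ndarray  # clean waveform p(t), unit amplitude
    drift_trace: np.ndarray  # additive drift per frame (intensity units)
    trajectory: np.ndarray  # (N, 2) patch offset (dx, dy) in px
    times_s: np.ndarray


@dataclass
class Scenario:
    """A fully specified synthetic recording condition.

    drift: ("none",) | ("linear", slope_per_s) | ("step", t_s, delta)
           | ("sine", f_hz, amp)
    motion: ("none",) | ("translate", dx_px_per_frame, dy_px_per_frame)
            | ("sway", amp_px, f_hz)
    """

    hr_hz: float = 1.2
    pulse_amp: tuple[float, float, float] = DEFAULT_PULSE_AMP
    base_color: tuple[float, float, float] = DEFAULT_BASE_COLOR
    drift: tuple = ("none",)
    motion: tuple = ("none",)
    specular_amp: float = 0.0
    specular_hz: float = 1.3
    noise_sigma: float = 2.0
    fps: float = 30.0
    duration_s: float = 20.0
    frame_size: tuple[int, int] = (120, 160)  # (H, W)
    patch_axes: tuple[float, float] | None = None  # (rx, ry) px; default from frame
    waveform: str = "sin"  # "sin" | "skewed"
    texture_rel: float = 0.02
    background_level: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        r, g, b = self.base_color
        if not (r > g > b):
            raise ConfigurationError("base_color must satisfy R > G > B (skin reflectance)")
        pixel = np.array(self.base_color, dtype=np.float64).reshape(1, 1, 3)
        if not detect_skin(pixel).mask[0, 0]:
            raise ConfigurationError(
                f"base_color {self.base_color} fails the H/Cb/Cr skin gate; "
                "the pipeline could never see the patch"
            )
        if self.motion[0] == "translate":
            step = float(np.hypot(self.motion[1], self.motion[2]))
            if step > 2.0:
                raise ConfigurationError("per-frame motion must stay within 2 px")


def _pulse_waveform(phase: np.ndarray, kind: str) -> np.ndarray:
    """Unit-amplitude pulse waveform as a function of phase (radians)."""
    if kind == "sin":
        return np.sin(phase)
    if kind == "skewed":
        # fast-systole shape: phase-modulated sine with unequal crest slopes
        return np.sin(phase - 0.35 * np.sin(phase))
    raise ConfigurationError(f"unknown waveform {kind!r}")


def _drift_trace(drift: tuple, t: np.ndarray) -> np.ndarray:
    kind = drift[0]
    if kind == "none":
        return np.zeros_like(t)
    if kind == "linear":
        return drift[1] * t
    if kind == "step":
        return np.where(t >= drift[1], float(drift[2]), 0.0)
    if kind == "sine":
        return drift[2] * np.sin(2.0 * np.pi * drift[1] * t)
    raise ConfigurationError(f"unknown drift profile {drift!r}")


def _trajectory(motion: tuple, t: np.ndarray) -> np.ndarray:
    n = len(t)
    if motion[0] == "none":
        return np.zeros((n, 2))
    if motion[0] == "translate":
        frames = np.arange(n, dtype=np.float64)
        return np.stack([motion[1] * frames, motion[2] * frames], axis=1)
    if motion[0] == "sway":
        amp, f = float(motion[1]), float(motion[2])
        dx = amp * np.sin(2.0 * np.pi * f * t)
        dy = 0.3 * amp * np.sin(2.0 * np.pi * f * t + 1.0)
        return np.stack([dx, dy], axis=1)
    raise ConfigurationError(f"unknown motion profile {motion!r}")


def generate(scenario: Scenario) -> tuple[FrameSequence, GroundTruth]:
    """Render the scenario into frames plus its ground truth."""
    sc = scenario
    h, w = sc.frame_size
    n = int(round(sc.duration_s * sc.fps))
    t = np.arange(n) / sc.fps
    rng = np.random.default_rng(sc.seed)

    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    pulse = _pulse_waveform(2.0 * np.pi * sc.hr_hz * t + phase0, sc.waveform)
    drift = _drift_trace(sc.drift, t)
    traj = _trajectory(sc.motion, t)
    specular = (
        sc.specular_amp * np.sin(2.0 * np.pi * sc.specular_hz * t + rng.uniform(0, 2 * np.pi))
        if sc.specular_amp
        else np.zeros_like(t)
    )

    # static scene layers -------------------------------------------------
    bg = sc.background_level + 12.0 * _smooth_noise(rng, (h, w), 3.0)
    # pixel-scale multiplicative skin texture (pores/sensor pattern), rigid
    # with the patch; sharp enough that motion shifts it visibly
    texture = sc.texture_rel * _smooth_noise(rng, (h, w), 1.2)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if sc.patch_axes is None:
        rx, ry = 0.28 * w, 0.27 * h
    else:
        rx, ry = sc.patch_axes
    edge = 0.06  # soft antialiased rim, ~1.5 px

    base = np.asarray(sc.base_color, dtype=np.float64)
    amp = np.asarray(sc.pulse_amp, dtype=np.float64)

    frames = np.empty((n, h, w, 3), dtype=np.uint8)
    moving = sc.motion[0] != "none"
    if not moving:
        e = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
        alpha0 = np.clip((1.0 - e) / edge, 0.0, 1.0)
        tex0 = texture
    for i in range(n):
        dx, dy = traj[i]
        if moving:
            e = ((xx - cx - dx) / rx) ** 2 + ((yy - cy - dy) / ry) ** 2
            alpha = np.clip((1.0 - e) / edge, 0.0, 1.0)
            tex = ndimage.map_coordinates(
                texture, [yy - dy, xx - dx], order=3, mode="nearest"
            )
        else:
            alpha, tex = alpha0, tex0
        modulation = 1.0 + tex + specular[i]
        frame = np.empty((h, w, 3))
        for c in range(3):
            patch_c = base[c] * (modulation + amp[c] * pulse[i])
            frame[..., c] = bg * (1.0 - alpha) + patch_c * alpha
        frame += drift[i] + rng.normal(0.0, sc.noise_sigma, size=(h, w, 3))
        frames[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    seq = FrameSequence(frames, sc.fps)
    truth = GroundTruth(
        hr_hz=sc.hr_hz,
        bpm_true=60.0 * sc.hr_hz,
        pulse_trace=pulse,
        drift_trace=drift,
        trajectory=traj,
        times_s=t,
    )
    return seq, truth


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Unit-variance spatially smoothed Gaussian field (fixed texture)."""
    field_ = ndimage.gaussian_filter(rng.normal(size=shape), sigma_px, mode="wrap")
    return field_ / field_.std()


def clean_roi_trace(scenario: Scenario, channel: int = 1) -> np.ndarray:
    """Noise-free ROI-mean trace of one channel (analysis helper).

    The spatial texture averages to ~0 over the patch, so the clean trace
    is base·(1 + ρ·p(t) + S(t)) + drift(t).
    """
    sc = scenario
    n = int(round(sc.duration_s * sc.fps))
    t = np.arange(n) / sc.fps
    rng = np.random.default_rng(sc.seed)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    pulse = _pulse_waveform(2.0 * np.pi * sc.hr_hz * t + phase0, sc.waveform)
    drift = _drift_trace(sc.drift, t)
    spec = (
        sc.specular_amp * np.sin(2 * np.pi * sc.specular_hz * t + rng.uniform(0, 2 * np.pi))
        if sc.specular_amp
        else 0.0
    )
    base = sc.base_color[channel]
    return base * (1.0 + sc.pulse_amp[channel] * pulse + spec) + drift


def scenario_grid(
    axis: str, levels: Sequence[float], base: Scenario | None = None
) -> list[Scenario]:
    """Map experimental-axis levels onto scenarios.

    ``distance`` (meters): the patch area shrinks with the square of the
    distance (reference 1 m fills the default patch), so farther subjects
    leave fewer skin pixels and proportionally more relative noise.
    ``lux``: brightness scales linearly toward the 300-lux reference and
    sensor noise grows as 1/sqrt(lux) (shot-noise-limited low light).
    """
    base = base or Scenario()
    h, w = base.frame_size
    out = []
    for level in levels:
        if axis == "distance":
            scale = 1.0 / float(level)
            out.append(
                replace(base, patch_axes=(0.28 * w * scale, 0.27 * h * scale))
            )
        elif axis == "lux":
            rel = float(level) / 300.0
            color = tuple(min(255.0, c * rel) for c in base.base_color)
            bg = base.background_level * rel
            sigma = base.noise_sigma / np.sqrt(rel)
            out.append(
                replace(
                    base,
                    base_color=color,
                    background_level=bg,
                    noise_sigma=float(sigma),
                )
            )
        else:
            raise ConfigurationError(f"unknown axis {axis!r}")
    return out
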