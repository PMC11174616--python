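"""Reading and writing video material for the heart-rate pipeline.

A recording is represented by :class:`FrameSequence`: a stack of H×W×3
frames in fixed R, G, B channel order on the 8-bit [0, 255] scale, plus a
uniform sampling rate. Frames are kept 8-bit on read and promoted to float
at the first arithmetic stage.

Two kinds of input are supported:

* a directory of lexicographically ordered, zero-padded PNG/BMP frames
  (the fps must be supplied, since bare images carry none);
* a video container (AVI/MP4), decoded through imageio when a platform
  plugin can handle it, using the container's (average) frame rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .errors import ConfigurationError, InputError, ValidationError

FRAME_SUFFIXES = (".png", ".bmp")


@dataclass
class FrameSequence:
    """An ordered stack of RGB frames sampled uniformly in time.

    Parameters
    ----------
    frames : ndarray, shape (N, H, W, 3)
        Pixel intensities in R, G, B order on the [0, 255] scale.
    fps : float
        Sampling rate in frames per second (Hz), > 0.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise InputError(
                f"expected an (N, H, W, 3) frame stack, got shape {self.frames.shape}"
            )
        if self.n_frames == 0:
            raise InputError("empty input: zero decodable frames")
        if not self.fps > 0:
            raise ConfigurationError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class ValidationReport:
    """Outcome of checking a sequence against the sampling requirements."""

    ok: bool
    violations: list[str] = field(default_factory=list)


def _read_frame_dir(path: Path, max_frames: int | None, fps: float | None) -> FrameSequence:
    if fps is None:
        raise ConfigurationError(
            f"{path} is a frame directory: an explicit fps is required (--fps)"
        )
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in FRAME_SUFFIXES)
    if max_frames is not None:
        files = files[:max_frames]
    if not files:
        raise InputError(f"no PNG/BMP frames found in {path}")
    frames = []
    shape = None
    for f in files:
        img = iio.imread(f)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        img = img[..., :3]
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise InputError(f"frame {f.name} has shape {img.shape}, expected {shape}")
        frames.append(img)
    return FrameSequence(np.stack(frames), float(fps))


def _read_container(path: Path, max_frames: int | None, fps: float | None) -> FrameSequence:
    try:
        meta = iio.immeta(path)
        frames = []
        for i, frame in enumerate(iio.imiter(path)):
            if max_frames is not None and i >= max_frames:
                break
            frames.append(np.asarray(frame)[..., :3])
    except Exception as exc:  # imageio raises plugin-specific errors
        raise InputError(f"could not decode {path}: {exc}") from exc
    if not frames:
        raise InputError(f"zero decodable frames in {path}")
    if fps is None:
        fps = meta.get("fps")
    if fps is None:
        raise ConfigurationError(f"{path}: container carries no fps; supply one explicitly")
    return FrameSequence(np.stack(frames), float(fps))


def read_video(
    path: str | Path, max_frames: int | None = None, fps: float | None = None
) -> FrameSequence:
    """Read a video container or a directory of numbered frames.

    ``fps`` overrides (and for frame directories must supply) the sampling
    rate. ``max_frames`` truncates the read after that many frames.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input path does not exist: {path}")
    if path.is_dir():
        return _read_frame_dir(path, max_frames, fps)
    return _read_container(path, max_frames, fps)


def write_frame_dir(seq: FrameSequence, path: str | Path) -> None:
    """Write a sequence as zero-padded PNG frames (lossless round trip)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = seq.frames
    if frames.dtype != np.uint8:
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    for i in range(seq.n_frames):
        iio.imwrite(path / f"frame_{i:06d}.png", frames[i])


def validate_input(
    seq: FrameSequence, min_fps: float = 30.0, min_duration: float = 20.0
) -> ValidationReport:
    """Check the sequence against the minimum sampling requirements.

    Reliable peak-interval heart-rate estimation needs at least 30 fps and
    20 s of material; shorter or slower recordings are reported here and
    rejected by the pipeline unless forced.
    """
    violations = []
    if seq.fps < min_fps:
        violations.append(f"fps {seq.fps:g} < required {min_fps:g}")
    # allow one frame period of slack on the duration
    if seq.duration_s < min_duration - 1.0 / seq.fps:
        violations.append(f"duration {seq.duration_s:.2f} s < required {min_duration:g} s")
    return ValidationReport(ok=not violations, violations=violations)


def require_valid(
    seq: FrameSequence, min_fps: float = 30.0, min_duration: float = 20.0, force: bool = False
) -> ValidationReport:
    """Raise :class:`ValidationError` unless the sequence passes (or ``force``)."""
    report = validate_input(seq, min_fps=min_fps, min_duration=min_duration)
    if not report.ok and not force:
        raise ValidationError("; ".join(report.violations))
    return report


def save_result_json(result: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result, indent=2, sort_keys=True))


def save_traces_csv(path: str | Path, times_s: Sequence[float], **columns) -> None:
    """Write per-stage traces as a simple CSV (time_s plus named columns)."""
    names = ["time_s", *columns]
    arrs = [np.asarray(times_s)] + [np.asarray(v) for v in columns.values()]
    with open(path, "w") as fh:
        fh.write(",".join(names) + "\n")
        for row in zip(*arrs):
            fh.write(",".join(f"{v:.6g}" for v in row) + "\n")
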