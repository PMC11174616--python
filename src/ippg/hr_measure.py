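"""Pulse extraction and heart-rate estimation.

The motion- and drift-stabilized R/G/B traces are normalized to unit
temporal mean, combined into two chrominance signals

    X_s = 3·R(n) − 2·G(n)
    Y_s = 1.5·R(n) + G(n) − 1.5·B(n)

band-pass filtered to X_f, Y_f, and recombined as S = X_f − α·Y_f with
α = std(X_f)/std(Y_f). The weighting is chosen so that a component shared
equally by all three channels (specular reflection, global illumination
residue) enters X_s and Y_s with equal amplitude and cancels in S, while
the pulsatile diffuse component survives.

The band-pass is a 257-tap linear-phase FIR with passband 0.8–1.9 Hz,
bracketing plausible heart rates (48–114 bpm); a recursive Butterworth of
realizable order is available for comparison. Filtering is group-delay
compensated (symmetric taps, centered convolution) so peak times stay on
video time; the first and last order/2 samples are warm-up transient and
excluded from peak search.

The heart rate is read from peak intervals: with peaks at t_1 < … < t_k,
every adjacent interval is one heartbeat cycle, the mean cycle is
(t_k − t_1)/(k − 1) (identical to the mean of adjacent intervals by
telescoping), and bpm = 60 / mean cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import (
    ConfigurationError,
    DegenerateSignalError,
    InputError,
    InsufficientSignalError,
)
from .spatial import ChannelTraces

DEFAULT_LOW_HZ = 0.8
DEFAULT_HIGH_HZ = 1.9
DEFAULT_ORDER = 256


@dataclass
class BandpassFilter:
    """A linear-phase FIR band-pass (taps sum over order+1 coefficients)."""

    taps: np.ndarray
    order: int
    passband: tuple[float, float]
    fs: float

    @property
    def group_delay_samples(self) -> int:
        return self.order // 2

    @property
    def transient_samples(self) -> int:
        """Samples at each end contaminated by filter warm-up."""
        return self.order // 2

    def apply(self, x: np.ndarray) -> np.ndarray:
        return apply_bandpass(self, x)

    def response_db(self, freqs_hz) -> np.ndarray:
        """Magnitude response in dB at the given frequencies (DTFT of the taps)."""
        _, h = sps.freqz(self.taps, worN=2 * np.pi * np.atleast_1d(freqs_hz) / self.fs)
        return 20.0 * np.log10(np.abs(h) + 1e-300)


def design_bandpass(
    fs: float = 30.0,
    low: float = DEFAULT_LOW_HZ,
    high: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
) -> BandpassFilter:
    """Design the default Hamming-windowed FIR band-pass (−6 dB edges at low/high)."""
    if not 0 < low < high:
        raise ConfigurationError(f"need 0 < low < high, got {low}, {high}")
    if high >= fs / 2:
        raise ConfigurationError(f"high edge {high} Hz violates Nyquist for fs={fs}")
    if order % 2 != 0:
        raise ConfigurationError(f"order must be even for a type-I FIR, got {order}")
    taps = sps.firwin(order + 1, [low, high], pass_zero=False, window="hamming", fs=fs)
    return BandpassFilter(taps=taps, order=order, passband=(low, high), fs=fs)


@dataclass
class ButterworthBandpass:
    """Realizable recursive Butterworth (second-order sections).

    Applied forward-backward, so it is zero-phase like the FIR default;
    kept as a comparison filter (``filter.type = "butter:<N>"``).
    """

    sos: np.ndarray
    order: int
    passband: tuple[float, float]
    fs: float

    @property
    def transient_samples(self) -> int:
        # edge transients decay on the scale of a few low-edge periods
        return int(round(2.0 * self.fs / self.passband[0]))

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return sps.sosfiltfilt(self.sos, x - x.mean())

    def response_db(self, freqs_hz) -> np.ndarray:
        _, h = sps.sosfreqz(self.sos, worN=2 * np.pi * np.atleast_1d(freqs_hz) / self.fs)
        # forward-backward application squares the magnitude response
        return 2.0 * 20.0 * np.log10(np.abs(h) + 1e-300)


def design_butterworth_sos(
    fs: float = 30.0,
    low: float = DEFAULT_LOW_HZ,
    high: float = DEFAULT_HIGH_HZ,
    order: int = 4,
) -> ButterworthBandpass:
    """Design the comparison Butterworth band-pass (order <= 10)."""
    if order > 10 or order < 1:
        raise ConfigurationError("recursive Butterworth order must be in 1..10")
    if high >= fs / 2:
        raise ConfigurationError(f"high edge {high} Hz violates Nyquist for fs={fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return ButterworthBandpass(sos=sos, order=order, passband=(low, high), fs=fs)


def apply_bandpass(filt: BandpassFilter, x: np.ndarray) -> np.ndarray:
    """Band-pass ``x`` with zero effective delay.

    The temporal mean is removed first (the filter blocks DC anyway; this
    keeps the implicit zero-padding at the ends from injecting a large
    step transient), then the signal is convolved with the symmetric taps
    in centered ('same') mode, which compensates the order/2 group delay.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) <= filt.order:
        raise ConfigurationError(
            f"signal length {len(x)} must exceed the filter order {filt.order}"
        )
    return np.convolve(x - x.mean(), filt.taps, mode="same")


@dataclass
class PulseSignal:
    """The recombined, standardized pulse signal S.

    ``valid`` marks the sample range free of filter warm-up transients;
    peak detection is restricted to it. Standardization maps the signal to
    the [−0.5, 0.5] span about its median without moving peak locations.
    """

    s: np.ndarray
    fs: float
    standardized: bool = True
    valid: tuple[int, int] = (0, -1)
    alpha: float = float("nan")

    def __post_init__(self) -> None:
        if self.valid == (0, -1):
            self.valid = (0, len(self.s))

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.s)) / self.fs


def standardize(x: np.ndarray) -> np.ndarray:
    """Center on the median and scale the span into [−0.5, 0.5]."""
    x = np.asarray(x, dtype=np.float64)
    x0 = x - np.median(x)
    amp = np.max(np.abs(x0))
    if amp == 0:
        raise DegenerateSignalError("signal has zero span; nothing to standardize")
    return x0 / (2.0 * amp)


def normalize_channels(traces: ChannelTraces) -> ChannelTraces:
    """Divide each channel by its temporal mean, yielding unit-mean signals."""
    out = []
    for name, arr in (("R", traces.r), ("G", traces.g), ("B", traces.b)):
        m = float(np.mean(arr))
        if abs(m) < 1e-12:
            raise DegenerateSignalError(f"{name} channel has zero temporal mean")
        out.append(np.asarray(arr, dtype=np.float64) / m)
    return ChannelTraces(out[0], out[1], out[2], traces.fps)


def chrome_combine(
    traces: ChannelTraces,
    filt: BandpassFilter | ButterworthBandpass,
    alpha_mode: str = "std_ratio",
) -> PulseSignal:
    """Form the chrominance pair, filter, and recombine into the pulse signal.

    ``alpha_mode`` is either ``"std_ratio"`` (α = std(X_f)/std(Y_f),
    equalizing artifact amplitude so the difference cancels it) or
    ``"fixed:<value>"``.
    """
    r, g, b = traces.r, traces.g, traces.b
    xs = 3.0 * r - 2.0 * g
    ys = 1.5 * r + g - 1.5 * b
    xf = filt.apply(xs)
    yf = filt.apply(ys)
    if alpha_mode == "std_ratio":
        sy = float(np.std(yf))
        if sy == 0:
            raise DegenerateSignalError("std(Y_f) = 0; cannot form alpha")
        alpha = float(np.std(xf)) / sy
    elif alpha_mode.startswith("fixed:"):
        alpha = float(alpha_mode.split(":", 1)[1])
    else:
        raise ConfigurationError(f"unknown alpha_mode {alpha_mode!r}")
    s = xf - alpha * yf
    margin = filt.transient_samples
    lo, hi = margin, len(s) - margin
    if hi <= lo:
        raise ConfigurationError("signal too short after excluding filter transients")
    return PulseSignal(s=standardize(s), fs=traces.fps, valid=(lo, hi), alpha=alpha)


def detect_peaks(
    sig: PulseSignal,
    min_prominence: float = 0.1,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> np.ndarray:
    """Locate beat peaks; returns their times in seconds at sample resolution.

    Local maxima must be separated by at least 1/``high_hz`` seconds (no
    two beats faster than the passband's upper edge) and have prominence
    of at least ``min_prominence`` of the signal span. Only the
    transient-free ``valid`` range is searched.
    """
    lo, hi = sig.valid
    s = np.asarray(sig.s[lo:hi], dtype=np.float64)
    if len(s) < 2:
        raise InsufficientSignalError("signal too short for peak detection")
    span = float(s.max() - s.min())
    if span == 0:
        raise InsufficientSignalError("constant signal: no peaks")
    distance = max(1, int(np.floor(sig.fs / high_hz)))
    idx, _ = sps.find_peaks(s, distance=distance, prominence=min_prominence * span)
    if len(idx) < 2:
        raise InsufficientSignalError(f"only {len(idx)} peak(s) found; need at least 2")
    return (idx + lo) / sig.fs


@dataclass
class HeartRateResult:
    """A heart-rate estimate with its supporting beat timing."""

    bpm: float
    n_cycles: int
    mean_cycle_s: float
    peak_times_s: np.ndarray = field(repr=False)


def estimate_heart_rate(peak_times_s) -> HeartRateResult:
    """Average the inter-peak intervals into a single bpm figure.

    Each adjacent-peak interval is one heartbeat cycle; their mean equals
    (last − first)/n_cycles by telescoping. The bpm is reported to 0.1.
    """
    t = np.asarray(peak_times_s, dtype=np.float64)
    if len(t) < 2:
        raise InsufficientSignalError("need at least 2 peaks to form a cycle")
    if np.any(np.diff(t) <= 0):
        raise InputError("peak times must be strictly increasing")
    n_cycles = len(t) - 1
    mean_cycle = (t[-1] - t[0]) / n_cycles
    bpm = round(60.0 / mean_cycle, 1)
    return HeartRateResult(
        bpm=bpm, n_cycles=n_cycles, mean_cycle_s=mean_cycle, peak_times_s=t
    )
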