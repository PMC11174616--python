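import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ippg import errors, hr_measure
from ippg.spatial import ChannelTraces


def dtft_db(taps, f_hz, fs):
    """Independent transfer-function oracle: direct DTFT sum of the taps."""
    k = np.arange(len(taps))
    h = np.sum(taps * np.exp(-2j * np.pi * f_hz * k / fs))
    return 20 * np.log10(abs(h) + 1e-300)


class TestBandpassDesign:
    def test_order_256_gives_257_taps(self):
        filt = hr_measure.design_bandpass()
        assert len(filt.taps) == 257
        assert filt.group_delay_samples == 128

    def test_passband_center_and_stopband_gains(self):
        filt = hr_measure.design_bandpass(fs=30, low=0.8, high=1.9, order=256)
        assert abs(dtft_db(filt.taps, 1.35, 30)) < 1.0
        assert dtft_db(filt.taps, 0.2, 30) < -20.0
        assert dtft_db(filt.taps, 5.0, 30) < -20.0
        assert dtft_db(filt.taps, 0.0, 30) < -40.0  # DC blocked

    def test_response_db_matches_dtft_oracle(self):
        filt = hr_measure.design_bandpass()
        for f in (0.2, 0.8, 1.35, 1.9, 5.0):
            assert filt.response_db(f)[0] == pytest.approx(dtft_db(filt.taps, f, 30), abs=1e-6)

    def test_nyquist_violation_raises(self):
        with pytest.raises(errors.ConfigurationError):
            hr_measure.design_bandpass(fs=30, low=0.8, high=16.0)

    def test_odd_order_rejected(self):
        with pytest.raises(errors.ConfigurationError):
            hr_measure.design_bandpass(order=255)


class TestNormalizeChannels:
    def test_constant_trace_becomes_unit(self):
        traces = ChannelTraces(np.full(10, 80.0), np.full(10, 80.0), np.full(10, 80.0), 30)
        out = hr_measure.normalize_channels(traces)
        np.testing.assert_allclose(out.r, 1.0)

    def test_mean_division(self):
        arr = np.array([90.0, 110.0])
        traces = ChannelTraces(arr, arr, arr, 30)
        out = hr_measure.normalize_channels(traces)
        np.testing.assert_allclose(out.g, [0.9, 1.1])

    def test_zero_mean_channel_is_degenerate(self):
        traces = ChannelTraces(np.zeros(10), np.ones(10), np.ones(10), 30)
        with pytest.raises(errors.DegenerateSignalError):
            hr_measure.normalize_channels(traces)


class TestChromeCombine:
    fs = 30.0

    def _traces(self, r, g, b):
        return ChannelTraces(r, g, b, self.fs)

    def test_constant_channels_are_degenerate(self):
        ones = np.ones(600)
        filt = hr_measure.design_bandpass()
        with pytest.raises(errors.DegenerateSignalError):
            hr_measure.chrome_combine(self._traces(ones, ones, ones), filt)

    def test_pulse_only_in_green_survives_as_scaled_copy(self):
        """R=B=1, G=1+p: X_s = 1-2p, Y_s = 1+p, so S must reproduce -p."""
        t = np.arange(600) / self.fs
        p = 0.01 * np.sin(2 * np.pi * 1.2 * t)
        filt = hr_measure.design_bandpass()
        sig = hr_measure.chrome_combine(
            self._traces(np.ones(600), 1.0 + p, np.ones(600)), filt
        )
        lo, hi = sig.valid
        corr = np.corrcoef(sig.s[lo:hi], -p[lo:hi])[0, 1]
        assert corr > 0.99
        # alpha = std(-2 p_f)/std(p_f) = 2 for a pulse confined to G
        assert sig.alpha == pytest.approx(2.0, abs=0.05)

    def test_shared_artifact_is_suppressed_relative_to_pulse(self):
        """An additive component common to all three channels cancels in
        X_f - alpha Y_f, while a G-only pulse five times weaker survives."""
        t = np.arange(600) / self.fs
        artifact = 0.02 * np.sin(2 * np.pi * 1.45 * t)
        p = 0.004 * np.sin(2 * np.pi * 1.1 * t)
        sig = hr_measure.chrome_combine(
            self._traces(1 + artifact, 1 + artifact + p, 1 + artifact),
            hr_measure.design_bandpass(),
        )
        lo, hi = sig.valid
        spec = np.abs(np.fft.rfft(sig.s[lo:hi]))
        freqs = np.fft.rfftfreq(hi - lo, 1 / self.fs)
        at = lambda f: spec[np.argmin(np.abs(freqs - f))]
        assert at(1.45) < 0.25 * at(1.1)

    def test_standardized_output_spans_at_most_unit_range(self, rng):
        t = np.arange(600) / self.fs
        g = 1 + 0.01 * np.sin(2 * np.pi * 1.3 * t) + 0.001 * rng.normal(size=600)
        sig = hr_measure.chrome_combine(
            self._traces(np.ones(600), g, np.ones(600)), hr_measure.design_bandpass()
        )
        assert sig.s.min() >= -0.5 - 1e-9
        assert sig.s.max() <= 0.5 + 1e-9

    def test_scaling_deviations_leaves_standardized_pulse_unchanged(self):
        """The combination is linear, so scaling all deviations rescales S
        and standardization removes the scale again."""
        t = np.arange(600) / self.fs
        p = 0.004 * np.sin(2 * np.pi * 1.25 * t)
        q = 0.002 * np.sin(2 * np.pi * 1.6 * t)
        filt = hr_measure.design_bandpass()
        s1 = hr_measure.chrome_combine(self._traces(1 + p, 1 - p + q, np.ones(600)), filt)
        s2 = hr_measure.chrome_combine(
            self._traces(1 + 3 * p, 1 - 3 * p + 3 * q, np.ones(600)), filt
        )
        np.testing.assert_allclose(s1.s, s2.s, atol=1e-9)

    def test_butterworth_comparison_filter_recovers_the_same_pulse(self):
        """The zero-phase recursive Butterworth option and the FIR default
        agree on the beat timing of a clean pulse."""
        t = np.arange(600) / self.fs
        p = 0.01 * np.sin(2 * np.pi * 1.2 * t)
        traces = self._traces(np.ones(600), 1 + p, np.ones(600))
        fir = hr_measure.chrome_combine(traces, hr_measure.design_bandpass())
        but = hr_measure.chrome_combine(traces, hr_measure.design_butterworth_sos())
        bpm_fir = hr_measure.estimate_heart_rate(hr_measure.detect_peaks(fir)).bpm
        bpm_but = hr_measure.estimate_heart_rate(hr_measure.detect_peaks(but)).bpm
        assert bpm_but == pytest.approx(bpm_fir, abs=0.5)
        assert bpm_but == pytest.approx(72.0, abs=1.0)

    def test_fixed_alpha_mode(self):
        t = np.arange(600) / self.fs
        p = 0.01 * np.sin(2 * np.pi * 1.2 * t)
        sig = hr_measure.chrome_combine(
            self._traces(np.ones(600), 1 + p, np.ones(600)),
            hr_measure.design_bandpass(),
            alpha_mode="fixed:1.0",
        )
        assert sig.alpha == 1.0


class TestDetectPeaks:
    def test_one_hz_sinusoid_gives_twenty_unit_cycles(self):
        t = np.arange(600) / 30.0
        sig = hr_measure.PulseSignal(hr_measure.standardize(np.sin(2 * np.pi * t)), 30.0)
        peaks = hr_measure.detect_peaks(sig)
        assert len(peaks) == 20
        np.testing.assert_allclose(np.diff(peaks), 1.0, atol=1 / 30 + 1e-9)

    def test_constant_signal_is_insufficient(self):
        sig = hr_measure.PulseSignal(np.zeros(600), 30.0)
        with pytest.raises(errors.InsufficientSignalError):
            hr_measure.detect_peaks(sig)

    def test_1p2_hz_interval(self):
        t = np.arange(600) / 30.0
        sig = hr_measure.PulseSignal(hr_measure.standardize(np.sin(2 * np.pi * 1.2 * t)), 30.0)
        intervals = np.diff(hr_measure.detect_peaks(sig))
        np.testing.assert_allclose(intervals, 1 / 1.2, atol=1 / 30 + 1e-9)

    def test_search_is_restricted_to_valid_range(self):
        t = np.arange(600) / 30.0
        s = hr_measure.standardize(np.sin(2 * np.pi * t))
        sig = hr_measure.PulseSignal(s, 30.0, valid=(128, 472))
        peaks = hr_measure.detect_peaks(sig)
        assert peaks.min() >= 128 / 30.0
        assert peaks.max() <= 472 / 30.0


class TestEstimateHeartRate:
    def test_printed_worked_example(self):
        """19 peaks spanning 18.82 s (18 cycles) must give 57.4 bpm."""
        res = hr_measure.estimate_heart_rate(np.linspace(0.0, 18.82, 19))
        assert res.bpm == 57.4
        assert res.n_cycles == 18
        assert res.mean_cycle_s == pytest.approx(18.82 / 18)

    @pytest.mark.parametrize(
        "peaks,bpm",
        [(np.arange(11.0), 60.0), (np.array([0.0, 0.5, 1.0]), 120.0)],
    )
    def test_uniform_cycles(self, peaks, bpm):
        assert hr_measure.estimate_heart_rate(peaks).bpm == bpm

    def test_non_monotonic_peaks_rejected(self):
        with pytest.raises(errors.InputError):
            hr_measure.estimate_heart_rate([0.0, 2.0, 1.0])

    def test_fewer_than_two_peaks_rejected(self):
        with pytest.raises(errors.InsufficientSignalError):
            hr_measure.estimate_heart_rate([1.0])

    @given(
        st.lists(st.floats(0.4, 2.0), min_size=2, max_size=40),
        st.floats(-100.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_interval_mean_telescopes_and_shift_invariance(self, intervals, shift):
        """The mean of adjacent intervals equals (last-first)/n exactly, and
        a global time shift leaves the estimate unchanged."""
        peaks = np.concatenate([[0.0], np.cumsum(intervals)])
        res = hr_measure.estimate_heart_rate(peaks)
        assert res.mean_cycle_s == pytest.approx(np.mean(np.diff(peaks)), rel=1e-12)
        shifted = hr_measure.estimate_heart_rate(peaks + shift)
        assert shifted.bpm == res.bpm
        assert shifted.n_cycles == res.n_cycles


class TestStandardize:
    def test_centered_on_median_within_half_unit(self, rng):
        x = rng.normal(size=500) * 7 + 3
        s = hr_measure.standardize(x)
        assert np.median(s) == pytest.approx(0.0, abs=1e-12)
        assert s.min() >= -0.5 and s.max() <= 0.5

    def test_zero_span_raises(self):
        with pytest.raises(errors.DegenerateSignalError):
            hr_measure.standardize(np.full(10, 3.3))
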