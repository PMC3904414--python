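"""EMG chain: filtering, RMS envelope, burst detection, stride selection,
normalization and set summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hiecod.emg import (EmgBurst, EmgRecording, InsufficientStridesError,
                        bandpass, detect_bursts, moving_rms,
                        normalize_amplitude, select_strides, sprint_reference,
                        summarize_set)

FS = 1000.0


def _recording(x: np.ndarray) -> EmgRecording:
    return EmgRecording(sampling_rate=FS, channel_names=("VL",),
                        data=x[np.newaxis, :])


def _tone(freq: float, n: int = 4000) -> np.ndarray:
    return np.sin(2 * np.pi * freq * np.arange(n) / FS)


def _amplitude_ratio(x_in: np.ndarray, x_out: np.ndarray, freq: float) -> float:
    """FFT amplitude of `freq` in output over input (oracle for filter gain)."""
    f = np.fft.rfftfreq(x_in.size, 1 / FS)
    k = np.argmin(np.abs(f - freq))
    return np.abs(np.fft.rfft(x_out))[k] / np.abs(np.fft.rfft(x_in))[k]


class TestBandpass:
    def test_passband_center_preserved(self):
        x = _tone(100.0)
        y = bandpass(_recording(x)).data[0]
        assert _amplitude_ratio(x, y, 100.0) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("freq", [5.0, 2.0])
    def test_low_frequencies_attenuated(self, freq):
        x = _tone(freq, 8000)
        y = bandpass(_recording(x)).data[0]
        assert _amplitude_ratio(x, y, freq) < 0.10

    def test_dc_removed(self):
        x = np.full(4000, 7.0)
        y = bandpass(_recording(x)).data[0]
        assert np.abs(y.mean()) < 1e-6

    def test_zero_phase_no_peak_shift(self):
        # a 100-Hz tone gated by a bump: the envelope peak must not move
        n = 4000
        env = np.zeros(n)
        env[1800:2200] = np.hanning(400)
        x = env * _tone(100.0, n)
        y = bandpass(_recording(x)).data[0]
        assert abs(int(np.argmax(np.abs(y))) - int(np.argmax(np.abs(x)))) <= 5

    def test_sampling_rate_too_low_rejected(self):
        rec = EmgRecording(sampling_rate=800.0, channel_names=("VL",),
                           data=np.zeros((1, 100)))
        with pytest.raises(ValueError):
            bandpass(rec)


class TestMovingRms:
    def test_constant_maps_to_itself(self):
        env = moving_rms(np.full(1000, 5.0), FS)
        assert np.allclose(env[100:-100], 5.0)

    def test_square_alternation(self):
        x = np.tile([3.0, -3.0], 500)
        env = moving_rms(x, FS)
        assert np.allclose(env[100:-100], 3.0, atol=1e-9)

    def test_white_noise_rms_estimates_sigma(self, rng):
        sigma = 2.5
        x = rng.normal(0, sigma, size=20000)
        env = moving_rms(x, FS, window_s=1.0)
        assert env[10000] == pytest.approx(sigma, rel=0.05)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            moving_rms(np.zeros(10), FS, window_s=0.05)


def _bump_envelope(onsets, amp, n, duration_s=0.2):
    env = np.zeros(n)
    for onset in onsets:
        i0 = int(onset * FS)
        m = int(duration_s * FS)
        tau = np.arange(m) / FS
        env[i0:i0 + m] += amp * 0.5 * (1 - np.cos(2 * np.pi * tau / duration_s))
    return env


class TestDetectBursts:
    def test_flat_envelope_at_baseline_gives_no_bursts(self, rng):
        quiet = rng.normal(0, 1.0, size=500)
        env = np.full(2000, np.abs(quiet).mean())
        assert detect_bursts(env, FS, quiet) == []

    def test_bump_train_recovered_with_accurate_onsets(self, rng):
        # clean bump train far above the baseline: every bump is found and
        # the threshold crossing sits within 10 ms of the true support start
        sigma = 0.05
        quiet = rng.normal(0, sigma, size=500)
        onsets = 0.1 + 0.3 * np.arange(10)
        env = _bump_envelope(onsets, amp=10.0, n=3300)
        bursts = detect_bursts(env, FS, quiet, smear_s=0.0)
        assert len(bursts) == 10
        errors_ms = 1000 * (np.array([b.onset for b in bursts]) - onsets)
        assert np.all(np.abs(errors_ms) <= 10.0)
        for b in bursts:
            assert b.offset > b.onset
            assert 0 < b.mean_rms <= b.peak_rms

    def test_bump_train_at_ten_sd_all_counted(self, rng):
        # at 10x the baseline SD the threshold crossing moves into the slow
        # raised-cosine rise, but every bump is still segmented exactly once
        sigma = 1.0
        quiet = rng.normal(0, sigma, size=500)
        onsets = 0.1 + 0.3 * np.arange(10)
        env = _bump_envelope(onsets, amp=10 * sigma, n=3300)
        env += np.abs(rng.normal(0, 0.05 * sigma, size=env.size))
        bursts = detect_bursts(env, FS, quiet, smear_s=0.0)
        assert len(bursts) == 10

    def test_bump_shorter_than_minimum_duration_dropped(self, rng):
        quiet = rng.normal(0, 1.0, size=500)
        env = _bump_envelope([0.5], amp=10.0, n=2000, duration_s=0.04)
        assert detect_bursts(env, FS, quiet) == []

    def test_envelope_entirely_above_threshold_flagged(self, rng):
        quiet = rng.normal(0, 1.0, size=500)
        env = np.full(2000, 50.0)
        bursts = detect_bursts(env, FS, quiet)
        assert len(bursts) == 1
        assert bursts[0].spans_window

    def test_quiet_period_too_short_rejected(self):
        with pytest.raises(Exception):
            detect_bursts(np.zeros(1000), FS, np.zeros(100))

    def test_raising_signal_never_reduces_burst_count(self, rng):
        # sub-threshold baseline has zero bursts; lifting it above threshold
        # can only create activity
        quiet = rng.normal(0, 1.0, size=500)
        env = np.full(2000, 0.5)
        assert len(detect_bursts(env, FS, quiet)) == 0
        assert len(detect_bursts(env + 10.0, FS, quiet)) >= 1


def _burst(peak, i, mean=None):
    return EmgBurst(channel="VL", onset=float(i), offset=float(i) + 0.2,
                    peak_rms=peak, mean_rms=mean if mean is not None else 0.6 * peak)


def _brute_force_min_cv(peaks, k):
    """Oracle: exhaustive scan of all consecutive windows."""
    best, best_key = None, None
    mid = (len(peaks) - 1) / 2
    for start in range(len(peaks) - k + 1):
        win = np.asarray(peaks[start:start + k])
        cv = win.std() / win.mean()
        key = (round(cv, 12), abs(start + (k - 1) / 2 - mid), start)
        if best_key is None or key < best_key:
            best, best_key = start, key
    return best


class TestSelectStrides:
    def test_exactly_five_returned_unchanged(self):
        bursts = [_burst(10.0, i) for i in range(5)]
        assert select_strides(bursts) == bursts

    def test_identical_peaks_pick_centered_window(self):
        bursts = [_burst(10.0, i) for i in range(11)]
        chosen = select_strides(bursts)
        assert [b.onset for b in chosen] == [3.0, 4.0, 5.0, 6.0, 7.0]

    def test_outlier_near_middle_excluded(self):
        peaks = [10, 10, 10, 10, 10, 40, 10, 10, 10, 10, 10, 10]
        bursts = [_burst(float(p), i) for i, p in enumerate(peaks)]
        chosen = select_strides(bursts)
        assert 40.0 not in [b.peak_rms for b in chosen]
        start = _brute_force_min_cv(peaks, 5)
        assert [b.onset for b in chosen] == [float(i) for i in range(start, start + 5)]

    @given(st.lists(st.floats(1.0, 100.0), min_size=6, max_size=15))
    def test_matches_exhaustive_oracle(self, peaks):
        bursts = [_burst(p, i) for i, p in enumerate(peaks)]
        chosen = select_strides(bursts)
        start = _brute_force_min_cv(peaks, 5)
        assert chosen == bursts[start:start + 5]

    def test_too_few_bursts_raises(self):
        with pytest.raises(InsufficientStridesError):
            select_strides([_burst(10.0, i) for i in range(4)])


class TestSprintReference:
    def test_five_equal_bursts(self):
        bursts = [_burst(20.0, i, mean=10.0) for i in range(5)]
        refs = sprint_reference({"VL": bursts})
        assert refs["VL"] == pytest.approx(10.0)

    def test_five_largest_of_seven(self):
        # oracle: manual mean of the five largest-peak contractions
        means = [6.0, 8.0, 9.0, 10.0, 11.0, 12.0, 7.0]
        peaks = [12.0, 16.0, 18.0, 20.0, 22.0, 24.0, 14.0]
        bursts = [_burst(p, i, mean=m) for i, (p, m) in enumerate(zip(peaks, means))]
        refs = sprint_reference({"VL": bursts})
        assert refs["VL"] == pytest.approx(np.mean([8, 9, 10, 11, 12]))

    def test_channel_failure_isolated(self):
        good = [_burst(20.0, i, mean=10.0) for i in range(5)]
        with pytest.raises(InsufficientStridesError, match="ST"):
            sprint_reference({"ST": good[:2], "VL": good})


class TestNormalizeAndSummarize:
    def test_normalization_basic(self):
        assert normalize_amplitude(10.0, 10.0) == pytest.approx(100.0)
        assert normalize_amplitude(5.0, 10.0) == pytest.approx(50.0)
        with pytest.raises(ValueError):
            normalize_amplitude(5.0, 0.0)

    @given(mean=st.floats(0.1, 1e3), ref=st.floats(0.1, 1e3), c=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, mean, ref, c):
        assert normalize_amplitude(c * mean, c * ref) == pytest.approx(
            normalize_amplitude(mean, ref), rel=1e-9)

    def test_set_summary_means(self):
        assert summarize_set([[80.0] * 5, [80.0] * 5]) == pytest.approx(80.0)
        assert summarize_set([[90.0] * 5, [80.0] * 5, [70.0] * 5]) == pytest.approx(80.0)
        assert summarize_set([[90.0] * 5, None, [70.0] * 5]) == pytest.approx(80.0)
        assert np.isnan(summarize_set([None, None]))
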