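"""Signal cleaning: band-pass behaviour, CAR, median filter, ROI cutting."""
import warnings

import numpy as np
import pytest
from scipy import ndimage

from microfusion.signals import (
    FilterSpec,
    SignalRoi,
    bandpass,
    common_average_reference,
    default_median_kernel,
    extract_signal_roi,
    frame_to_sample,
    median_filter_gsr,
    normalize,
    trim_lead,
)


def tone(freq, rate, seconds=8.0):
    t = np.arange(int(seconds * rate)) / rate
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    RATE = 256.0

    def test_in_band_tone_preserved(self):
        x = tone(10, self.RATE)
        y = bandpass(x, self.RATE, 1.0, 45.0)
        rms_in = np.sqrt((x[256:-256] ** 2).mean())
        rms_out = np.sqrt((y[256:-256] ** 2).mean())
        assert abs(rms_out / rms_in - 1.0) < 0.05

    def test_out_of_band_tone_attenuated_20db(self):
        x = tone(60, self.RATE)
        y = bandpass(x, self.RATE, 1.0, 45.0)
        # interior samples: edge transients are not steady-state behaviour
        sl = slice(256, -256)
        ratio = np.sqrt((y[sl] ** 2).mean() / (x[sl] ** 2).mean())
        assert 20 * np.log10(1.0 / ratio) >= 20.0

    def test_zero_signal_stays_zero(self):
        assert np.allclose(bandpass(np.zeros(1024), self.RATE, 1, 45), 0.0)

    def test_linearity(self, rng):
        x = rng.normal(size=2048)
        a = 3.7
        assert np.allclose(bandpass(a * x, self.RATE, 1, 45),
                           a * bandpass(x, self.RATE, 1, 45), atol=1e-8)

    def test_high_cut_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(1024), 128.0, 1.0, 64.0)

    def test_matrix_input_filters_each_channel(self, rng):
        x = rng.normal(size=(4, 2048))
        y = bandpass(x, self.RATE, 1, 45)
        for c in range(4):
            assert np.allclose(y[c], bandpass(x[c], self.RATE, 1, 45))

    def test_filterspec_validation(self):
        with pytest.raises(ValueError):
            FilterSpec(kind="bandpass", low_hz=10.0, high_hz=5.0)
        with pytest.raises(ValueError):
            FilterSpec(kind="median", kernel_samples=4)

    def test_apply_filter_dispatches(self, rng):
        from microfusion.signals import apply_filter

        x = rng.normal(size=1024)
        bp = FilterSpec(kind="bandpass", low_hz=1.0, high_hz=45.0)
        assert np.allclose(apply_filter(x, 256.0, bp), bandpass(x, 256.0, 1.0, 45.0))
        med = FilterSpec(kind="median", kernel_samples=5)
        assert np.allclose(apply_filter(x, 256.0, med), median_filter_gsr(x, 5))


class TestCar:
    def test_two_channel_hand_example(self):
        eeg = np.array([[1.0, 1.0], [3.0, 3.0]])
        out = common_average_reference(eeg)
        assert np.array_equal(out, np.array([[-1.0, -1.0], [1.0, 1.0]]))

    def test_column_means_vanish(self, rng):
        out = common_average_reference(rng.normal(size=(32, 1000)))
        assert np.abs(out.mean(axis=0)).max() < 1e-10

    def test_equals_per_sample_loop_oracle(self, rng):
        eeg = rng.normal(size=(32, 1000))
        expected = np.empty_like(eeg)
        for s in range(eeg.shape[1]):  # brute-force oracle
            expected[:, s] = eeg[:, s] - eeg[:, s].mean()
        assert np.abs(common_average_reference(eeg) - expected).max() < 1e-10

    def test_idempotent(self, rng):
        eeg = rng.normal(size=(8, 500))
        once = common_average_reference(eeg)
        assert np.allclose(common_average_reference(once), once, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(np.zeros((1, 100)))


class TestMedianFilter:
    def test_spike_removed(self):
        assert np.array_equal(
            median_filter_gsr(np.array([0.0, 0, 9, 0, 0]), 3), np.zeros(5))

    def test_monotone_ramp_unchanged_except_edges(self):
        ramp = np.arange(20.0)
        out = median_filter_gsr(ramp, 5)
        assert np.array_equal(out[2:-2], ramp[2:-2])

    def test_equals_naive_oracle(self, rng):
        x = rng.normal(size=200)
        k = 7
        got = median_filter_gsr(x, k)
        pad = k // 2
        xp = np.concatenate([x[pad - 1 :: -1] if pad else x[:0], x, x[: -pad - 1 : -1]])
        expected = np.array([np.median(xp[i : i + k]) for i in range(x.size)])
        assert np.abs(got - expected).max() < 1e-10

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            median_filter_gsr(np.zeros(10), 4)

    def test_default_kernel_is_odd(self):
        for rate in (100.0, 128.0, 125.0):
            assert default_median_kernel(rate) % 2 == 1


class TestNormalize:
    def test_simple_vector(self):
        out = normalize(np.array([1.0, 2.0, 3.0]))
        assert abs(out.mean()) < 1e-10 and abs(out.std() - 1) < 1e-10

    def test_constant_channel_becomes_zero_with_warning(self):
        with pytest.warns(UserWarning):
            out = normalize(np.full((2, 10), 5.0))
        assert np.array_equal(out, np.zeros((2, 10)))

    def test_per_channel_invariant(self, rng):
        out = normalize(rng.normal(2.0, 3.0, size=(6, 400)))
        assert np.abs(out.mean(axis=1)).max() < 1e-10
        assert np.abs(out.std(axis=1) - 1).max() < 1e-10


class TestTrimAndMapping:
    def test_trim_arithmetic(self):
        x = np.zeros(63 * 128)
        assert trim_lead(x, 128.0, 8.0).shape[0] == 7040

    def test_trim_zero_is_identity(self, rng):
        x = rng.normal(size=100)
        assert np.array_equal(trim_lead(x, 128.0, 0.0), x)

    def test_short_trial_rejected(self):
        with pytest.raises(ValueError):
            trim_lead(np.zeros(5 * 128), 128.0, 8.0)

    @pytest.mark.parametrize(
        "frame,fps,rate,expected",
        [(1500, 50.0, 128.0, 3840), (0, 30.0, 128.0, 0), (900, 30.0, 128.0, 3840)],
    )
    def test_frame_to_sample(self, frame, fps, rate, expected):
        assert frame_to_sample(frame, fps, rate) == expected


class TestSignalRoi:
    def test_centered_window(self):
        x = np.zeros(40 * 128)
        roi, data = extract_signal_roi(x, 128.0, 20 * 128, 15.0)
        assert data.shape[-1] == 1920
        assert roi.start_sample == 20 * 128 - 960
        assert roi.end_sample == 20 * 128 + 960

    def test_boundary_shift(self):
        x = np.zeros(40 * 128)
        roi, data = extract_signal_roi(x, 128.0, 10, 15.0)
        assert (roi.start_sample, roi.end_sample) == (0, 1920)

    def test_all_returns_full_trial(self, rng):
        x = rng.normal(size=500)
        roi, data = extract_signal_roi(x, 128.0, 250, "all")
        assert np.array_equal(data, x)
        assert roi.n_samples == 500

    def test_too_long_rejected(self):
        with pytest.raises(ValueError):
            extract_signal_roi(np.zeros(100), 128.0, 50, 15.0)

    @pytest.mark.parametrize("seconds", [1.0, 7.5, 14.9])
    def test_length_always_exact(self, rng, seconds):
        x = rng.normal(size=(3, 15 * 128))
        apex = int(rng.integers(0, x.shape[-1]))
        _, data = extract_signal_roi(x, 128.0, apex, seconds)
        assert data.shape == (3, int(round(seconds * 128)))
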