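"""Conditioning chain: upsampling, median detrending, normalization, snippets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import drivebeat as db
from drivebeat import preprocess as pp


def _channel(x, fs=500.0, modality="ecg_ref"):
    return db.Channel(np.asarray(x, dtype=float), fs, modality)


class TestUpsample:
    def test_length_arithmetic_10_to_500(self):
        ch = _channel(np.sin(np.arange(100) / 10), fs=10, modality="ippg_green")
        out = pp.upsample(ch, 500)
        assert len(out) == 5000 and out.fs == 500

    def test_identity_at_target_rate(self):
        ch = _channel(np.random.default_rng(0).normal(size=200))
        out = pp.upsample(ch, 500)
        np.testing.assert_array_equal(out.samples, ch.samples)

    def test_grid_values_preserved(self):
        ch = _channel(np.arange(50, dtype=float), fs=10, modality="ippg_green")
        out = pp.upsample(ch, 500)
        np.testing.assert_allclose(out.samples[::50], ch.samples, atol=1e-12)

    def test_spectral_peak_preserved(self):
        """A 1 Hz sine keeps its dominant DFT frequency after upsampling."""
        t = np.arange(300) / 10.0
        ch = _channel(np.sin(2 * np.pi * 1.0 * t), fs=10, modality="ippg_green")
        out = pp.upsample(ch, 500)
        spec = np.abs(np.fft.rfft(out.samples - out.samples.mean()))
        freqs = np.fft.rfftfreq(len(out), 1 / 500)
        assert abs(freqs[np.argmax(spec)] - 1.0) <= freqs[1]

    def test_downsampling_rejected(self):
        with pytest.raises(db.SignalError):
            pp.upsample(_channel(np.zeros(100)), 250)

    def test_polyphase_matches_linear_on_smooth_signal(self):
        t = np.arange(200) / 10.0
        ch = _channel(np.sin(2 * np.pi * 0.5 * t), fs=10, modality="ippg_green")
        a = pp.upsample(ch, 500, method="linear")
        b = pp.upsample(ch, 500, method="polyphase")
        # agree away from the edges
        assert np.median(np.abs(a.samples[500:-500] - b.samples[500:-500])) < 0.01


def brute_force_running_median(x: np.ndarray, window: int) -> np.ndarray:
    """O(L*window) reference: edge replication, lower-median for even windows.

    The window at position i covers [i - window//2, i + (window-1)//2]
    (scipy centering), indices clipped to the signal (edge replication).
    """
    left = window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        lo = i - left
        idx = np.clip(np.arange(lo, lo + window), 0, x.size - 1)
        out[i] = np.sort(x[idx])[(window - 1) // 2]
    return out


class TestDetrendMedian:
    def test_constant_maps_to_zero(self):
        out = pp.detrend_median(_channel(np.full(500, 5.0)), window=100)
        np.testing.assert_array_equal(out.samples, 0.0)

    def test_hand_enumerated_window3(self):
        out = pp.detrend_median(_channel([1, 1, 9, 1, 1]), window=3)
        np.testing.assert_array_equal(out.samples, [0, 0, 8, 0, 0])

    def test_spike_survives_ramp_removed(self):
        x = np.linspace(0, 1, 400)
        x[200] += 5.0
        out = pp.detrend_median(_channel(x), window=100)
        assert out.samples[200] == pytest.approx(5.0, abs=0.2)
        off_spike = np.delete(out.samples[60:-60], 200 - 60)
        assert np.abs(off_spike).max() < 0.2

    @pytest.mark.parametrize("window", [3, 100])
    def test_equals_brute_force_on_random_signals(self, window, rng):
        for _ in range(5):
            x = rng.normal(size=300)
            out = pp.detrend_median(_channel(x), window=window)
            np.testing.assert_array_equal(
                out.samples, x - brute_force_running_median(x, window)
            )

    def test_smoothing_variant(self):
        x = np.random.default_rng(1).normal(size=300)
        sm = pp.detrend_median(_channel(x), window=5, subtract=False)
        np.testing.assert_array_equal(
            sm.samples, brute_force_running_median(x, 5)
        )

    def test_window_too_large_rejected(self):
        with pytest.raises(db.SignalError):
            pp.detrend_median(_channel(np.zeros(50)), window=50)


class TestNormalize:
    def test_affine_map(self):
        out = pp.normalize(_channel([0.0, 2.0, 4.0]))
        np.testing.assert_allclose(out.samples, [-1, 0, 1])

    def test_identity_on_endpoints(self):
        out = pp.normalize(_channel([-1.0, 1.0]))
        np.testing.assert_allclose(out.samples, [-1, 1])

    def test_constant_maps_to_zeros(self):
        out = pp.normalize(_channel([7.0, 7.0, 7.0]))
        np.testing.assert_array_equal(out.samples, 0.0)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_range_property(self, values):
        out = pp.normalize(_channel(values))
        if np.ptp(values) > 0:
            assert out.samples.min() == pytest.approx(-1)
            assert out.samples.max() == pytest.approx(1)
        else:
            np.testing.assert_array_equal(out.samples, 0.0)


class TestSnippetSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        chans = [
            db.Channel(rng.normal(size=900), 500, m)
            for m in ("ecg_wheel", "ppg")
        ]
        truth = db.BeatTrain(np.array([0.8, 1.4]))
        s = pp.extract_snippets(chans, truth, mode="train")
        pp.save_snippets(s, tmp_path / "snips")
        back = pp.load_snippets(tmp_path / "snips")
        np.testing.assert_array_equal(back.X, s.X)
        np.testing.assert_array_equal(back.y, s.y)
        np.testing.assert_array_equal(back.starts, s.starts)
        assert back.signals == s.signals and back.step == s.step


class TestExtractSnippets:
    def _signals(self, length, n=1):
        rng = np.random.default_rng(0)
        return [
            db.Channel(rng.normal(size=length), 500, db.MODALITIES[i])
            for i in range(n)
        ]

    def test_boundary_single_snippet(self):
        s = pp.extract_snippets(self._signals(501), None, mode="test")
        assert s.n_snippets == 1

    def test_train_step_count(self):
        s = pp.extract_snippets(self._signals(1000), None, mode="train")
        assert s.step == 11
        assert s.n_snippets == (1000 - 501) // 11 + 1 == 46

    def test_test_step_count_equals_enumeration(self):
        s = pp.extract_snippets(self._signals(1000), None, mode="test")
        starts = [i for i in range(1000) if i + 501 <= 1000]
        assert s.n_snippets == len(starts) == 500
        np.testing.assert_array_equal(s.starts, starts)

    @pytest.mark.parametrize("mode,step", [("train", 11), ("test", 1)])
    def test_count_formula_random_lengths(self, mode, step, rng):
        for length in rng.integers(501, 5000, size=10):
            s = pp.extract_snippets(self._signals(int(length)), None, mode=mode)
            assert s.n_snippets == (length - 501) // step + 1

    def test_too_short_rejected(self):
        with pytest.raises(db.SignalError):
            pp.extract_snippets(self._signals(500), None, mode="test")

    def test_snippet_content_matches_source(self):
        chans = self._signals(700, n=2)
        s = pp.extract_snippets(chans, None, mode="train")
        j = 3
        for k, ch in enumerate(chans):
            np.testing.assert_allclose(
                s.X[j, :, k],
                ch.samples[s.starts[j] : s.starts[j] + 501],
                rtol=1e-6,
            )

    def test_labeling_window_rule(self):
        """y_j = 1 iff a beat lies within 25 samples of the snippet center."""
        length = 2000
        chans = self._signals(length)
        truth = db.BeatTrain(np.array([1.5]))  # sample 750
        s = pp.extract_snippets(chans, truth, mode="test")
        centers = s.starts + 250
        expected = (np.abs(centers - 750) <= 25).astype(np.int8)
        np.testing.assert_array_equal(s.y, expected)

    def test_each_inner_beat_labels_at_least_one_snippet(self, small_recording):
        ch = pp.preprocess_channel(small_recording["ecg_wheel"])
        s = pp.extract_snippets([ch], small_recording.truth, mode="test")
        beat_idx = small_recording.truth.to_samples(500)
        inner = beat_idx[(beat_idx >= 275) & (beat_idx <= len(ch) - 275)]
        assert s.y.sum() >= inner.size

    def test_mismatched_channels_rejected(self):
        a = db.Channel(np.zeros(600), 500, "ecg_ref")
        b = db.Channel(np.zeros(700), 500, "ppg")
        with pytest.raises(db.SignalError):
            pp.extract_snippets([a, b], None, mode="test")
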