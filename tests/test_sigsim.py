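"""Simulator: beat trains, waveform rendering, artifacts, full recordings."""

import numpy as np
import pytest

import drivebeat as db
from drivebeat.sigsim import PPG_TEMPLATE_PEAK_OFFSET


class TestGenerateBeatTrain:
    def test_zero_variance_is_a_metronome(self, metronome_beats):
        assert len(metronome_beats) == 60
        np.testing.assert_allclose(
            np.diff(metronome_beats.beat_times), 1.0, atol=1e-9
        )

    def test_same_seed_identical(self):
        a = db.generate_beat_train(10, 60, 5, seed=1)
        b = db.generate_beat_train(10, 60, 5, seed=1)
        np.testing.assert_array_equal(a.beat_times, b.beat_times)

    def test_different_seed_differs(self):
        a = db.generate_beat_train(30, 60, 5, seed=1)
        b = db.generate_beat_train(30, 60, 5, seed=2)
        assert not np.array_equal(a.beat_times, b.beat_times)

    def test_beat_count_matches_oracle_redraw(self):
        """Count over 600 s at 75 bpm within 3 SE of the expected 750.

        Oracle: re-draw RR intervals with the same generator and count how
        many cumulative sums stay within the duration.
        """
        duration, hr, sd, seed = 600.0, 75.0, 3.0, 7
        train = db.generate_beat_train(duration, hr, sd, seed)
        rng = np.random.default_rng(seed)
        rr_mean, rr_sd = 60.0 / hr, 60.0 * sd / hr**2
        rr = np.clip(rng.normal(rr_mean, rr_sd, size=2000), 0.25, None)
        oracle_count = int(np.sum(np.cumsum(rr) <= duration))
        expected = duration / rr_mean
        se = np.sqrt(expected) * rr_sd / rr_mean
        assert abs(len(train) - expected) <= max(3 * se, 3)
        assert len(train) == oracle_count

    def test_invariants(self):
        t = db.generate_beat_train(300, 180, 30, seed=3)
        dt = np.diff(t.beat_times)
        assert np.all(dt >= 0.25 - 1e-9)
        assert np.all(dt > 0)

    @pytest.mark.parametrize("duration,hr", [(-1, 60), (0, 60), (10, 10), (10, 300)])
    def test_invalid_arguments(self, duration, hr):
        with pytest.raises(db.SignalError):
            db.generate_beat_train(duration, hr, 0, seed=0)


class TestSynthEcg:
    def test_noise_free_peaks_at_beats(self):
        beats = db.BeatTrain(np.array([1.0, 2.0]))
        ch = db.synth_ecg(beats, 500, 0, seed=0, duration=2.6)
        for idx in (500, 1000):
            local = np.argmax(ch.samples[idx - 25 : idx + 26]) + idx - 25
            assert abs(local - idx) <= 1

    def test_r_dominates_other_waves(self, clean_ecg, metronome_beats):
        idx = metronome_beats.to_samples(500)
        r_amp = clean_ecg.samples[idx].min()
        # everything more than 60 ms away from any R peak
        far = np.ones(len(clean_ecg), dtype=bool)
        for i in idx:
            far[max(0, i - 30) : i + 30] = False
        assert r_amp >= 3 * np.abs(clean_ecg.samples[far]).max()

    def test_deterministic_with_noise(self, metronome_beats):
        a = db.synth_ecg(metronome_beats, 500, 0.05, seed=9)
        b = db.synth_ecg(metronome_beats, 500, 0.05, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_r_amplitude_under_noise_monte_carlo(self):
        """R-peak sample ~ template amplitude +/- 3 noise_sd for >=99% of beats."""
        beats = db.generate_beat_train(20, 60, 0, seed=0)
        idx = beats.to_samples(500)
        noise = 0.05
        hits = total = 0
        for seed in range(20):
            ch = db.synth_ecg(beats, 500, noise, seed=seed)
            amp = ch.samples[idx]
            hits += int(np.sum(np.abs(amp - 1.0) <= 3 * noise + 1e-3))
            total += idx.size
        assert hits / total >= 0.99

    def test_empty_beats_rejected(self):
        with pytest.raises(db.SignalError):
            db.synth_ecg(db.BeatTrain(np.array([])), 500, 0, 0, duration=5)


class TestSynthPpg:
    def test_pulse_peak_at_delay_plus_template_offset(self):
        beats = db.BeatTrain(np.array([1.0]))
        ch = db.synth_ppg(beats, 500, delay=0.2, noise_sd=0, seed=0, duration=3)
        expected = int(round((1.0 + 0.2 + PPG_TEMPLATE_PEAK_OFFSET) * 500))
        assert abs(int(np.argmax(ch.samples)) - expected) <= 1

    def test_zero_delay_peak_equals_template_offset(self):
        beats = db.BeatTrain(np.array([1.0]))
        ch = db.synth_ppg(beats, 500, delay=0.0, noise_sd=0, seed=0, duration=3)
        expected = int(round((1.0 + PPG_TEMPLATE_PEAK_OFFSET) * 500))
        assert abs(int(np.argmax(ch.samples)) - expected) <= 1

    def test_ecg_ppg_lag_equals_delay_plus_offset(self, metronome_beats):
        """Brute-force cross-correlation lag between ECG and PPG."""
        delay = 0.25
        ecg = db.synth_ecg(metronome_beats, 500, 0, 0, duration=61)
        ppg = db.synth_ppg(metronome_beats, 500, delay, 0, 0, duration=61)
        e = ecg.samples - ecg.samples.mean()
        p = ppg.samples - ppg.samples.mean()
        max_lag = 300
        lags = np.arange(0, max_lag)
        cc = np.array([np.dot(e[: e.size - l], p[l:]) for l in lags])
        best = int(lags[np.argmax(cc)])
        expected = int(round((delay + PPG_TEMPLATE_PEAK_OFFSET) * 500))
        assert abs(best - expected) <= 1

    def test_delay_out_of_range(self, metronome_beats):
        with pytest.raises(db.SignalError):
            db.synth_ppg(metronome_beats, 500, delay=0.9)


class TestSynthIppg:
    def test_dominant_frequency_is_heart_rate(self, metronome_beats):
        ch = db.synth_ippg(metronome_beats, 10, 0, seed=0)
        spec = np.abs(np.fft.rfft(ch.samples - ch.samples.mean()))
        freqs = np.fft.rfftfreq(len(ch), 1 / 10)
        dominant = freqs[np.argmax(spec)]
        assert abs(dominant - 1.0) <= freqs[1]  # one DFT bin

    def test_mean_equals_illumination_constant(self, metronome_beats):
        ch = db.synth_ippg(metronome_beats, 10, 0, seed=0, illumination=1.7)
        assert ch.samples.mean() == pytest.approx(1.7, abs=1e-9)

    def test_modality_tag(self, metronome_beats):
        assert db.synth_ippg(metronome_beats, 10, 0, 0).modality == "ippg_green"

    def test_nyquist_rejected(self):
        fast = db.generate_beat_train(30, 150, 0, seed=0)  # 2.5 Hz pulse
        with pytest.raises(db.SignalError):
            db.synth_ippg(fast, 4, 0, 0)

    def test_snr_decreases_with_noise(self, metronome_beats):
        """Pulse-band over out-of-band power ratio falls as noise rises."""
        snrs = []
        for noise in (0.01, 0.1, 1.0):
            ch = db.synth_ippg(metronome_beats, 10, noise, seed=5)
            x = ch.samples - ch.samples.mean()
            spec = np.abs(np.fft.rfft(x)) ** 2
            freqs = np.fft.rfftfreq(len(ch), 1 / 10)
            band = (freqs >= 0.8) & (freqs <= 1.2)
            snrs.append(spec[band].sum() / spec[~band][1:].sum())
        assert snrs[0] > snrs[1] > snrs[2]


class TestAddDrivingArtifacts:
    def test_zero_parameters_is_identity(self, metronome_beats):
        ch = db.synth_ecg(metronome_beats, 500, 0, 0)
        cfg = db.SimConfig(
            duration=60, baseline_amp=0, burst_rate=0, dropout_rate=0,
            noise_sd={m: 0.0 for m in db.MODALITIES},
        )
        out = db.add_driving_artifacts(ch, cfg, seed=0)
        np.testing.assert_array_equal(out.samples, ch.samples)
        assert not out.artifact_mask.any()

    def test_input_unmodified(self, metronome_beats):
        ch = db.synth_ecg(metronome_beats, 500, 0, 0)
        before = ch.samples.copy()
        db.add_driving_artifacts(ch, db.SimConfig(duration=60), seed=0)
        np.testing.assert_array_equal(ch.samples, before)

    def test_burst_count_matches_poisson_oracle(self):
        """Expected 4 bursts in 60 s; 200-seed mean within 3 SE."""
        beats = db.generate_beat_train(60, 60, 0, 0)
        ch = db.synth_ecg(beats, 100, 0, 0, duration=60.5)
        cfg = db.SimConfig(
            duration=60, burst_rate=4.0, baseline_amp=0, dropout_rate=0,
            noise_sd={"ecg_ref": 0.1},
        )
        counts = []
        for seed in range(200):
            out = db.add_driving_artifacts(ch, cfg, seed=seed)
            # count mask runs (bursts never overlap dropouts here)
            m = out.artifact_mask.astype(int)
            counts.append(int(np.sum(np.diff(np.concatenate([[0], m])) == 1)))
        lam = 4.0 * 60.5 / 60.0
        se = np.sqrt(lam / 200)
        # merged adjacent bursts only reduce the run count
        assert lam - 4 * se <= np.mean(counts) <= lam + 3 * se

    def test_dropout_samples_constant(self):
        beats = db.generate_beat_train(30, 60, 0, 0)
        ch = db.synth_ecg(beats, 500, 0, 0)
        cfg = db.SimConfig(
            duration=30, baseline_amp=0, burst_rate=0, dropout_rate=20,
            noise_sd={m: 0.0 for m in db.MODALITIES},
        )
        out = db.add_driving_artifacts(ch, cfg, seed=3)
        mask = out.artifact_mask
        assert mask.any()
        edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int)])) == 1)
        for lo in edges:
            hi = lo
            while hi < mask.size and mask[hi]:
                hi += 1
            assert np.unique(out.samples[lo:hi]).size == 1


class TestSimulateRecording:
    def test_deterministic(self):
        cfg = db.SimConfig(duration=20, seed=42)
        a = db.simulate_recording(cfg)
        b = db.simulate_recording(cfg)
        for m in db.MODALITIES:
            np.testing.assert_array_equal(a[m].samples, b[m].samples)
        np.testing.assert_array_equal(a.truth.beat_times, b.truth.beat_times)

    def test_counter_ratio_ecg_to_ippg(self, small_recording):
        ecg_c = small_recording["ecg_ref"].counter
        ippg_c = small_recording["ippg_green"].counter
        assert np.all(ippg_c % 50 == 0)
        # every iPPG counter value exists on the ECG master clock
        assert np.isin(ippg_c[ippg_c <= ecg_c[-1]], ecg_c).all()
        np.testing.assert_array_equal(np.diff(ippg_c), 50)

    def test_reference_ecg_is_clean_by_default(self, small_recording):
        assert small_recording["ecg_ref"].artifact_mask is None

    def test_channels_and_truth_present(self, small_recording):
        assert set(small_recording.channels) == set(db.MODALITIES)
        assert len(small_recording.truth) > 20
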