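import numpy as np
import pytest

import drivebeat as db


@pytest.fixture(scope="session")
def metronome_beats():
    """60 s of beats at exactly 1 Hz (zero rate variance)."""
    return db.generate_beat_train(60, 60, 0, seed=0)


@pytest.fixture(scope="session")
def clean_ecg(metronome_beats):
    return db.synth_ecg(metronome_beats, 500, 0, seed=0, duration=60.5)


@pytest.fixture(scope="session")
def small_recording():
    """30 s mildly noisy recording with all four channels."""
    cfg = db.SimConfig(duration=30, hr_mean=72, hr_sd=2, seed=11)
    return db.simulate_recording(cfg, subject_id="sub-11")


@pytest.fixture(scope="session")
def clean_recording():
    """45 s artifact-free recording (zero noise, no bursts/dropouts)."""
    cfg = db.SimConfig(
        duration=45,
        hr_mean=66,
        hr_sd=2,
        noise_sd={m: 0.0 for m in db.MODALITIES},
        baseline_amp=0.0,
        burst_rate=0.0,
        dropout_rate=0.0,
        seed=21,
    )
    return db.simulate_recording(cfg, subject_id="sub-21")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
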