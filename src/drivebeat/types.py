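"""Core domain containers shared across the pipeline.

The pipeline models a driver monitored by redundant cardiac sensors: a clean
reference ECG (chest electrodes), a noisy steering-wheel ECG, a contact PPG on
the wheel rim, and an image-based PPG (iPPG) derived from the green channel of
a face video.  All containers are thin dataclasses around NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: minimal physiological spacing between heartbeats (refractory floor), seconds
REFRACTORY_S = 0.25

#: canonical modality tags, in the fixed stacking order used for snippets
MODALITIES = ("ecg_ref", "ecg_wheel", "ppg", "ippg_green")

SCENARIOS = ("city", "highway", "countryside")


class SignalError(ValueError):
    """Raised for malformed or degenerate signal inputs."""


@dataclass(frozen=True)
class BeatTrain:
    """Ordered ground-truth heartbeat times in seconds from recording start.

    Invariants: strictly increasing, with consecutive differences of at least
    ``REFRACTORY_S`` (0.25 s, i.e. an instantaneous rate below 240 bpm).
    """

    beat_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "beat_times", t)
        if t.ndim != 1:
            raise SignalError("beat_times must be one-dimensional")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise SignalError("beat times must be strictly increasing")
            if np.any(dt < REFRACTORY_S - 1e-9):
                raise SignalError(
                    f"RR interval below refractory floor {REFRACTORY_S} s"
                )

    def __len__(self) -> int:
        return int(self.beat_times.size)

    def to_samples(self, fs: float) -> np.ndarray:
        """Beat positions as integer sample indices at rate ``fs``."""
        return np.round(self.beat_times * fs).astype(np.int64)


@dataclass
class Channel:
    """One modality's sample array.

    ``samples`` are mV for ECG and arbitrary units (a.u.) for PPG/iPPG.  The
    optional ``counter`` carries the acquisition system's shared ascending
    sample counter used for cross-modality synchronization; it is strictly
    increasing but not necessarily contiguous (the 10 Hz iPPG channel holds
    every 50th value of the master 500 Hz clock).
    """

    samples: np.ndarray
    fs: float
    modality: str
    counter: Optional[np.ndarray] = None
    artifact_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise SignalError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise SignalError("samples must all be finite")
        if self.modality not in MODALITIES:
            raise SignalError(f"unknown modality {self.modality!r}")
        if self.fs <= 0:
            raise SignalError("sampling rate must be positive")
        if self.counter is not None:
            self.counter = np.asarray(self.counter, dtype=np.int64)
            if self.counter.shape != self.samples.shape:
                raise SignalError("counter must have one entry per sample")
            if self.counter.size >= 2 and np.any(np.diff(self.counter) <= 0):
                raise SignalError("counter must be strictly increasing")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def copy(self) -> "Channel":
        return replace(
            self,
            samples=self.samples.copy(),
            counter=None if self.counter is None else self.counter.copy(),
            artifact_mask=None
            if self.artifact_mask is None
            else self.artifact_mask.copy(),
        )


@dataclass
class Recording:
    """All synchronized channels of one subject in one driving scenario."""

    subject_id: str
    scenario: str
    channels: dict[str, Channel] = field(default_factory=dict)
    truth: Optional[BeatTrain] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise SignalError(f"unknown scenario {self.scenario!r}")
        for tag, ch in self.channels.items():
            if tag != ch.modality:
                raise SignalError(
                    f"channel stored under {tag!r} has modality {ch.modality!r}"
                )

    def __getitem__(self, modality: str) -> Channel:
        return self.channels[modality]
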