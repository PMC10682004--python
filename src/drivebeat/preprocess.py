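"""Signal conditioning and snippet construction.

The conditioning chain is fixed: (i) up-sample every channel to the master
500 Hz clock, (ii) subtract a 100-sample running-median baseline estimate,
(iii) normalize amplitudes to [-1, 1].  The conditioned, synchronized signals
are then cut into 501-sample snippets — overlapping by 490 samples for
training (step 11) and by 500 for testing (step 1) — and binary-labeled by
heartbeat presence.

A snippet is labeled 1 iff a reference R peak lies within ``label_halfwidth``
samples (default 25, i.e. 50 ms) of the snippet's center sample.  With test
step 1 this makes each beat the center of a contiguous run of positive
snippets, which is what makes decoding labels back into beat positions
well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import rank_filter
from scipy.signal import resample_poly

from .types import BeatTrain, Channel, SignalError

__all__ = [
    "SnippetSet",
    "upsample",
    "detrend_median",
    "normalize",
    "extract_snippets",
    "preprocess_channel",
    "SNIPPET_LEN",
    "TRAIN_STEP",
    "TEST_STEP",
    "LABEL_HALFWIDTH",
]

SNIPPET_LEN = 501
TRAIN_STEP = SNIPPET_LEN - 490  # training snippets overlap by 490 samples
TEST_STEP = SNIPPET_LEN - 500  # testing snippets overlap by 500 samples
LABEL_HALFWIDTH = 25  # 50 ms at 500 Hz


@dataclass
class SnippetSet:
    """Windowed multi-signal matrix with binary heartbeat labels.

    ``X`` has shape [n_snippets, snippet_len, n_signals] (float32), signals
    stacked in a fixed modality order recorded in ``signals``.  ``starts``
    are the snippet start indices on the 500 Hz clock and form an arithmetic
    sequence with common difference ``step``.
    """

    X: np.ndarray
    y: np.ndarray
    starts: np.ndarray
    step: int
    signals: tuple[str, ...]
    snippet_len: int = SNIPPET_LEN
    fs: float = 500.0

    def __post_init__(self) -> None:
        if self.X.ndim != 3:
            raise SignalError("X must be [n_snippets, snippet_len, n_signals]")
        if self.X.shape[0] != self.y.size or self.X.shape[0] != self.starts.size:
            raise SignalError("X, y, starts must agree on n_snippets")
        if self.starts.size >= 2:
            d = np.diff(self.starts)
            if not np.all(d == self.step):
                raise SignalError("starts must be arithmetic with difference step")

    @property
    def n_snippets(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_signals(self) -> int:
        return int(self.X.shape[2])

    def centers(self) -> np.ndarray:
        """Center sample index of each snippet on the 500 Hz clock."""
        return self.starts + self.snippet_len // 2


def save_snippets(s: SnippetSet, path) -> None:
    """Serialize a snippet set: .npz array container + .json sidecar.

    The sidecar carries the metadata (starts, step, labels, modality order)
    in plain text; the arrays go into the compressed container.
    """
    import json
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), X=s.X, y=s.y, starts=s.starts)
    sidecar = {
        "step": int(s.step),
        "snippet_len": int(s.snippet_len),
        "fs": float(s.fs),
        "signals": list(s.signals),
        "n_snippets": int(s.n_snippets),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_snippets(path) -> SnippetSet:
    """Inverse of :func:`save_snippets`."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        X, y, starts = z["X"], z["y"], z["starts"]
    return SnippetSet(X, y, starts, meta["step"], tuple(meta["signals"]),
                      meta["snippet_len"], meta["fs"])


def upsample(ch: Channel, target_fs: float = 500.0, method: str = "linear") -> Channel:
    """Resample a channel up to ``target_fs`` (default the master 500 Hz).

    ``linear`` interpolation (default) preserves original sample values at
    their grid positions and peak locations at these rates; ``polyphase``
    selects scipy's FIR polyphase resampler.  Down-sampling is rejected.
    """
    if target_fs < ch.fs:
        raise SignalError("downsampling not supported; target_fs below channel fs")
    if target_fs == ch.fs:
        return ch.copy()
    ratio = target_fs / ch.fs
    n_out = int(round(len(ch) * ratio))
    if method == "linear":
        t_out = np.arange(n_out) / target_fs
        t_in = np.arange(len(ch)) / ch.fs
        x = np.interp(t_out, t_in, ch.samples)
    elif method == "polyphase":
        from fractions import Fraction

        frac = Fraction(target_fs / ch.fs).limit_denominator(1000)
        x = resample_poly(ch.samples, frac.numerator, frac.denominator)[:n_out]
    else:
        raise SignalError(f"unknown upsampling method {method!r}")
    counter = None
    if ch.counter is not None:
        # original counters sit every `ratio` samples on the new grid
        step = int(round(ratio))
        counter = ch.counter[0] * step + np.arange(n_out, dtype=np.int64)
    return Channel(x, target_fs, ch.modality, counter)


def detrend_median(ch: Channel, window: int = 100, subtract: bool = True) -> Channel:
    """Running-median filter of size ``window``.

    By default the running median is treated as a baseline estimate and
    subtracted (so a constant signal maps to all zeros); with
    ``subtract=False`` the median-filtered signal itself is returned
    (smoothing).  Edges are handled by replication; an even window uses the
    lower-median convention.
    """
    if window < 3:
        raise SignalError("median window must be >= 3")
    if window >= len(ch):
        raise SignalError("median window must be smaller than the signal")
    baseline = rank_filter(ch.samples, rank=(window - 1) // 2, size=window,
                           mode="nearest")
    x = ch.samples - baseline if subtract else baseline
    return Channel(x, ch.fs, ch.modality,
                   None if ch.counter is None else ch.counter.copy())


def normalize(ch: Channel) -> Channel:
    """Affine-map amplitudes to [-1, 1]; a constant channel maps to zeros."""
    if len(ch) == 0:
        raise SignalError("cannot normalize an empty channel")
    lo, hi = ch.samples.min(), ch.samples.max()
    if hi == lo:
        x = np.zeros_like(ch.samples)
    else:
        x = 2.0 * (ch.samples - lo) / (hi - lo) - 1.0
    return Channel(x, ch.fs, ch.modality,
                   None if ch.counter is None else ch.counter.copy())


def preprocess_channel(ch: Channel, target_fs: float = 500.0,
                       median_window: int = 100) -> Channel:
    """Full conditioning chain: upsample -> median detrend -> normalize."""
    return normalize(detrend_median(upsample(ch, target_fs), median_window))


def snippet_count(length: int, step: int, snippet_len: int = SNIPPET_LEN) -> int:
    """Number of snippets of ``snippet_len`` fitting a signal of ``length``."""
    if length < snippet_len:
        raise SignalError(f"signal of length {length} shorter than a snippet")
    return (length - snippet_len) // step + 1


def extract_snippets(
    signals: Sequence[Channel],
    truth: BeatTrain | None,
    mode: str = "test",
    snippet_len: int = SNIPPET_LEN,
    label_halfwidth: int = LABEL_HALFWIDTH,
    dtype=np.float32,
) -> SnippetSet:
    """Cut synchronized channels into labeled overlapping snippets.

    ``mode='train'`` steps by 11 samples (overlap 490) to thin the training
    set; ``mode='test'`` steps by 1 (overlap 500) for sample-resolution
    decoding.  All channels must share fs and length.  ``truth`` may be None
    for unlabeled data (labels then all zero).
    """
    if mode == "train":
        step = snippet_len - 490
    elif mode == "test":
        step = snippet_len - 500
    else:
        raise SignalError(f"mode must be 'train' or 'test', got {mode!r}")
    if not signals:
        raise SignalError("need at least one channel")
    fs = signals[0].fs
    length = len(signals[0])
    for ch in signals[1:]:
        if ch.fs != fs or len(ch) != length:
            raise SignalError("all channels must share fs and length")
    n = snippet_count(length, step, snippet_len)
    starts = np.arange(n, dtype=np.int64) * step

    X = np.empty((n, snippet_len, len(signals)), dtype=dtype)
    for s, ch in enumerate(signals):
        win = np.lib.stride_tricks.sliding_window_view(ch.samples, snippet_len)
        X[:, :, s] = win[::step][:n]

    centers = starts + snippet_len // 2
    y = np.zeros(n, dtype=np.int8)
    if truth is not None and len(truth):
        beat_idx = truth.to_samples(fs)
        # nearest beat distance for every snippet center
        pos = np.searchsorted(beat_idx, centers)
        d_right = np.where(pos < beat_idx.size,
                           np.abs(beat_idx[np.minimum(pos, beat_idx.size - 1)]
                                  - centers), np.iinfo(np.int64).max)
        d_left = np.where(pos > 0,
                          np.abs(centers - beat_idx[np.maximum(pos - 1, 0)]),
                          np.iinfo(np.int64).max)
        y[np.minimum(d_left, d_right) <= label_halfwidth] = 1

    return SnippetSet(X, y, starts, step,
                      tuple(ch.modality for ch in signals), snippet_len, fs)
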