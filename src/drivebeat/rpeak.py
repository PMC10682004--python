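"""Ground-truth R-peak positions by detector consensus.

The reference chest ECG is high-SNR, so ground truth only needs a majority
vote over a few diverse QRS detectors rather than a full performance-level
estimation.  Three detectors are registered by default:

* ``pt``       — Pan–Tompkins style: band-pass, derivative, squaring,
  moving-window integration, adaptive threshold;
* ``deriv``    — slope-threshold detector with an adaptive amplitude gate;
* ``localmax`` — detrended local-maximum picker with a percentile threshold.

:func:`consensus` clusters candidates across detectors by single linkage
within a tolerance and emits one beat per cluster supported by a quorum of
distinct detectors, at the cluster's median position (ties toward the
earlier sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import REFRACTORY_S, BeatTrain, Channel, SignalError

__all__ = [
    "CandidateSet",
    "detect_pt",
    "detect_derivative",
    "detect_localmax",
    "consensus",
    "DETECTORS",
    "ground_truth_beats",
]


@dataclass(frozen=True)
class CandidateSet:
    """One detector's candidate R-peak positions (sample indices)."""

    detector_name: str
    positions: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", p)
        if p.size >= 2:
            d = np.diff(p)
            if np.any(d <= 0):
                raise SignalError("candidate positions must be strictly increasing")
            if np.any(d < REFRACTORY_S * self.fs - 1e-9):
                raise SignalError("candidate spacing below refractory floor")

    def __len__(self) -> int:
        return int(self.positions.size)

    def times(self) -> np.ndarray:
        return self.positions / self.fs


def _check_ecg(ch: Channel) -> None:
    if ch.modality not in ("ecg_ref", "ecg_wheel"):
        raise SignalError("R-peak detection requires an ECG channel")
    if ch.fs < 200:
        raise SignalError("ECG sampling rate must be >= 200 Hz")
    if ch.duration < 2.0:
        raise SignalError("signal too short for R-peak detection (< 2 s)")


def _normalize_polarity(x: np.ndarray) -> np.ndarray:
    """Flip the trace if R deflections point downward."""
    med = np.median(x)
    return x if np.max(x) - med >= med - np.min(x) else 2 * med - x


def _enforce_refractory(peaks: np.ndarray, strength: np.ndarray,
                        min_gap: int) -> np.ndarray:
    """Greedily keep the strongest of any pair closer than ``min_gap``."""
    if peaks.size == 0:
        return peaks
    order = np.argsort(strength)[::-1]
    keep: list[int] = []
    taken = np.zeros(peaks.size, dtype=bool)
    for i in order:
        p = peaks[i]
        if all(abs(p - peaks[j]) >= min_gap for j in keep):
            keep.append(i)
            taken[i] = True
    return np.sort(peaks[sorted(keep)])


def detect_pt(ch: Channel) -> CandidateSet:
    """Pan–Tompkins style QRS detection.

    Band-pass 5–15 Hz, differentiate, square, integrate over a 150 ms moving
    window, then pick integration peaks above an adaptive threshold and
    refine each to the nearest band-passed maximum.
    """
    _check_ecg(ch)
    fs = ch.fs
    x = _normalize_polarity(ch.samples - np.median(ch.samples))
    if np.ptp(x) == 0:
        return CandidateSet("pt", np.array([], dtype=np.int64), fs)
    sos = sps.butter(2, [5, 15], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    feat = np.convolve(np.gradient(bp) ** 2,
                       np.ones(int(0.150 * fs)) / int(0.150 * fs), mode="same")
    thr = 0.2 * np.percentile(feat, 99)
    if thr <= 0:
        return CandidateSet("pt", np.array([], dtype=np.int64), fs)
    min_gap = int(REFRACTORY_S * fs)
    peaks, _ = sps.find_peaks(feat, height=thr, distance=min_gap)
    # refine to the band-passed R maximum within +/-60 ms
    half = int(0.060 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=np.int64))
    refined = _enforce_refractory(refined, bp[refined], min_gap)
    return CandidateSet("pt", refined, fs)


def detect_derivative(ch: Channel) -> CandidateSet:
    """Slope-threshold detector with an adaptive amplitude gate.

    Marks samples whose absolute slope exceeds 3x the trace's robust slope
    scale and whose amplitude clears an adaptive gate at half the 99th
    amplitude percentile, then collapses each suprathreshold region to its
    amplitude maximum.
    """
    _check_ecg(ch)
    fs = ch.fs
    x = _normalize_polarity(ch.samples - np.median(ch.samples))
    if np.ptp(x) == 0:
        return CandidateSet("deriv", np.array([], dtype=np.int64), fs)
    slope = np.abs(np.gradient(x))
    slope_scale = np.median(slope) + 1e-12
    gate = 0.5 * np.percentile(x, 99.5)
    # amplitude gate: require a clearly positive deflection
    strong = (slope > 8.0 * slope_scale)
    if not np.any(strong) or gate <= 0:
        return CandidateSet("deriv", np.array([], dtype=np.int64), fs)
    min_gap = int(REFRACTORY_S * fs)
    peaks, _ = sps.find_peaks(x, height=gate, distance=min_gap)
    # keep peaks flanked by a steep slope within 40 ms
    half = int(0.040 * fs)
    ok = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        if np.any(strong[lo:hi]):
            ok.append(p)
    pos = np.asarray(ok, dtype=np.int64)
    pos = _enforce_refractory(pos, x[pos], min_gap)
    return CandidateSet("deriv", pos, fs)


def detect_localmax(ch: Channel) -> CandidateSet:
    """Detrended local-maximum picker with a percentile threshold.

    High-pass detrends with a 200 ms running-mean subtraction, then keeps
    local maxima above the 98th percentile of the detrended positive part,
    spaced by the refractory floor.
    """
    _check_ecg(ch)
    fs = ch.fs
    x = _normalize_polarity(ch.samples - np.median(ch.samples))
    if np.ptp(x) == 0:
        return CandidateSet("localmax", np.array([], dtype=np.int64), fs)
    w = max(3, int(0.200 * fs))
    baseline = np.convolve(x, np.ones(w) / w, mode="same")
    d = x - baseline
    pos_part = d[d > 0]
    if pos_part.size == 0:
        return CandidateSet("localmax", np.array([], dtype=np.int64), fs)
    thr = np.percentile(pos_part, 98)
    min_gap = int(REFRACTORY_S * fs)
    peaks, _ = sps.find_peaks(d, height=thr, distance=min_gap)
    peaks = _enforce_refractory(peaks.astype(np.int64), d[peaks], min_gap)
    return CandidateSet("localmax", peaks, fs)


DETECTORS = {
    "pt": detect_pt,
    "deriv": detect_derivative,
    "localmax": detect_localmax,
}


def consensus(
    cands: list[CandidateSet],
    tol_ms: float = 100.0,
    min_votes: int | None = None,
) -> BeatTrain:
    """Majority-vote consensus over detector candidate sets.

    Candidates from all detectors are pooled and clustered by single linkage:
    sorted positions chain into one cluster while consecutive gaps stay
    within ``tol_ms``.  A cluster supported by at least ``min_votes``
    distinct detectors (default: a strict majority, ceil(k/2)) emits one beat
    at the cluster's median position, ties broken toward the earlier sample.
    Emitted beats closer than the refractory floor keep the earlier one.
    """
    if len(cands) < 2:
        raise SignalError("consensus needs at least 2 candidate sets")
    k = len(cands)
    if min_votes is None:
        min_votes = (k + 1) // 2
    if min_votes > k:
        raise SignalError("min_votes exceeds the number of detectors")
    fs = cands[0].fs
    if any(c.fs != fs for c in cands):
        raise SignalError("candidate sets must share a sampling rate")

    pos = np.concatenate([c.positions for c in cands]) if cands else np.array([])
    who = np.concatenate(
        [np.full(len(c), i, dtype=np.int64) for i, c in enumerate(cands)]
    ) if cands else np.array([])
    if pos.size == 0:
        return BeatTrain(np.array([]))
    order = np.argsort(pos, kind="stable")
    pos, who = pos[order], who[order]

    tol = tol_ms / 1000.0 * fs
    breaks = np.flatnonzero(np.diff(pos) > tol) + 1
    beats: list[float] = []
    for cluster_pos, cluster_who in zip(
        np.split(pos, breaks), np.split(who, breaks)
    ):
        if np.unique(cluster_who).size >= min_votes:
            # median of member positions; half-integer medians floor toward
            # the earlier sample
            median_pos = int(np.floor(np.median(cluster_pos)))
            beats.append(median_pos / fs)

    # refractory suppression: keep the earlier beat
    kept: list[float] = []
    for t in beats:
        if not kept or t - kept[-1] >= REFRACTORY_S:
            kept.append(t)
    return BeatTrain(np.asarray(kept))


def ground_truth_beats(
    ch: Channel,
    detectors: tuple[str, ...] = ("pt", "deriv", "localmax"),
    tol_ms: float = 100.0,
    min_votes: int | None = None,
) -> BeatTrain:
    """Run the detector ensemble on a reference ECG and return the consensus."""
    cands = [DETECTORS[name](ch) for name in detectors]
    return consensus(cands, tol_ms=tol_ms, min_votes=min_votes)
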