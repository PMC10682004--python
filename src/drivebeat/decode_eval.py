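"""Beat decoding, reference matching, PPV/S/P metrics, and LOSO evaluation.

The classifiers emit one binary label per test snippet (step 1, so one label
per sample position).  Decoding turns maximal runs of consecutive positive
labels into beat positions; matching pairs detected and reference beats
within a tolerance; the evaluation statistic is

    P = (PPV + S) / 2,   PPV = TP / (TP + FP),   S = TP / (TP + FN),

the fraction of "usable time" in which the detected heartbeat positions
agree with the reference.  ``loso_evaluate`` drives the whole pipeline under
leave-one-subject-out cross-validation across an approaches x signal-sets
grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fusion, preprocess, rpeak
from .preprocess import LABEL_HALFWIDTH, SnippetSet
from .types import REFRACTORY_S, BeatTrain, Recording, SignalError

__all__ = [
    "DetectionResult",
    "EvalReport",
    "labels_to_beats",
    "match_beats",
    "compute_metrics",
    "evaluate_detection",
    "loso_evaluate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionResult:
    """Detected beat positions (sample indices at 500 Hz) with provenance."""

    positions: np.ndarray
    fs: float = 500.0
    approach: str = ""
    signals: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", p)
        if p.size >= 2:
            d = np.diff(p)
            if np.any(d <= 0):
                raise SignalError("detected positions must be strictly increasing")
            if np.any(d < REFRACTORY_S * self.fs - 1e-9):
                raise SignalError("detected beat spacing below refractory floor")

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class EvalReport:
    """TP/FP/FN counts and the derived PPV, sensitivity and P statistics."""

    TP: int
    FP: int
    FN: int
    PPV: float
    S: float
    P: float
    degenerate: bool = False


def labels_to_beats(
    labels: np.ndarray,
    starts: np.ndarray,
    step: int = 1,
    min_run: int = LABEL_HALFWIDTH,
    refractory_ms: float = 250.0,
    fs: float = 500.0,
    snippet_len: int = preprocess.SNIPPET_LEN,
    approach: str = "",
    signals: tuple[str, ...] = (),
) -> DetectionResult:
    """Decode per-snippet labels into beat positions.

    Each maximal run of consecutive 1-labels of length >= ``min_run`` emits
    one beat at the center sample of the run's center snippet (ties toward
    the earlier snippet).  Beats closer than the refractory interval to the
    previous emitted beat are suppressed, keeping the earlier one.  Requires
    test-mode labels (step 1), where a beat produces a contiguous positive
    run centered on it.
    """
    if step != 1:
        raise SignalError("decoding requires test-mode snippets (step 1)")
    labels = np.asarray(labels).astype(np.int8)
    starts = np.asarray(starts, dtype=np.int64)
    if labels.size != starts.size:
        raise SignalError("labels and starts must have equal length")
    half = snippet_len // 2
    padded = np.concatenate([[0], labels, [0]])
    edges = np.diff(padded)
    run_lo = np.flatnonzero(edges == 1)
    run_hi = np.flatnonzero(edges == -1)  # exclusive
    refractory = int(refractory_ms / 1000.0 * fs)
    beats: list[int] = []
    for lo, hi in zip(run_lo, run_hi):
        if hi - lo < min_run:
            continue
        center_snippet = (lo + hi - 1) // 2
        beat = int(starts[center_snippet]) + half
        if beats and beat - beats[-1] < refractory:
            continue  # keep the earlier beat
        beats.append(beat)
    return DetectionResult(np.asarray(beats, dtype=np.int64), fs, approach, signals)


def match_beats(
    detected: DetectionResult | np.ndarray,
    reference: BeatTrain | np.ndarray,
    tol_ms: float = 50.0,
    fs: float = 500.0,
) -> tuple[int, int, int]:
    """Greedy one-to-one nearest-neighbour matching within a tolerance.

    Walks references in order; each claims its nearest still-unmatched
    detection within ``tol_ms``.  Returns (TP, FP, FN) with
    TP + FN = len(reference) and TP + FP = len(detected).
    """
    if tol_ms < 0:
        raise SignalError("matching tolerance must be non-negative")
    if isinstance(detected, DetectionResult):
        det = detected.positions / detected.fs
    else:
        det = np.asarray(detected, dtype=float) / fs
    if isinstance(reference, BeatTrain):
        ref = reference.beat_times
    else:
        ref = np.asarray(reference, dtype=float) / fs
    tol = tol_ms / 1000.0 + 1e-9  # epsilon: distances exactly at tol match
    used = np.zeros(det.size, dtype=bool)
    tp = 0
    for r in ref:
        if det.size == 0:
            break
        d = np.abs(det - r)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            tp += 1
    return tp, int(det.size - tp), int(ref.size - tp)


def compute_metrics(TP: int, FP: int, FN: int) -> EvalReport:
    """PPV, sensitivity and the overall performance P = (PPV + S) / 2.

    If a denominator is zero (no detections, or no reference beats) the
    corresponding statistic is reported as 0 and the report is flagged
    degenerate, so fold averages stay defined.
    """
    if min(TP, FP, FN) < 0:
        raise SignalError("counts must be non-negative")
    degenerate = False
    if TP + FP > 0:
        ppv = TP / (TP + FP)
    else:
        ppv, degenerate = 0.0, True
    if TP + FN > 0:
        s = TP / (TP + FN)
    else:
        s, degenerate = 0.0, True
    return EvalReport(TP, FP, FN, ppv, s, (ppv + s) / 2.0, degenerate)


def evaluate_detection(
    detected: DetectionResult,
    reference: BeatTrain,
    tol_ms: float = 50.0,
) -> EvalReport:
    """Match detections to the reference and compute PPV/S/P in one step."""
    return compute_metrics(*match_beats(detected, reference, tol_ms))


def evaluate_split(
    train_recordings: list[Recording],
    test_recording: Recording,
    approach: str = "early",
    signals: tuple[str, ...] = ("ecg",),
    cfg: "fusion.FusionConfig | None" = None,
    tol_ms: float = 50.0,
) -> EvalReport:
    """Train on some recordings, test on one: a single cross-validation fold.

    Runs the full pipeline (condition -> snippets -> train -> predict ->
    decode -> match) for one approach and signal set.
    """
    cfg = cfg or fusion.FusionConfig()
    train_preps = [_prepare(r) for r in train_recordings]
    test_prep = _prepare(test_recording)
    return _run_fold(train_preps, test_prep, approach, tuple(signals), cfg, tol_ms)


# ---------------------------------------------------------------------------
# Leave-one-subject-out evaluation


_SIGNAL_TO_CHANNEL = {
    "ecg": "ecg_wheel",
    "ppg": "ppg",
    "ippg": "ippg_green",
}


@dataclass
class _PreparedSubject:
    subject_id: str
    scenario: str
    conditioned: dict[str, "preprocess.Channel"]
    reference: BeatTrain


def _prepare(rec: Recording) -> _PreparedSubject:
    """Condition all channels of one recording and derive its ground truth."""
    conditioned = {
        tag: preprocess.preprocess_channel(rec[chan])
        for tag, chan in _SIGNAL_TO_CHANNEL.items()
        if chan in rec.channels
    }
    reference = rpeak.ground_truth_beats(rec["ecg_ref"])
    return _PreparedSubject(rec.subject_id, rec.scenario, conditioned, reference)


def _snippets(
    prep: _PreparedSubject, signal_set: tuple[str, ...], mode: str
) -> SnippetSet:
    channels = [prep.conditioned[s] for s in signal_set]
    return preprocess.extract_snippets(channels, prep.reference, mode=mode)


def _concat_snippet_sets(sets: list[SnippetSet]) -> SnippetSet:
    X = np.concatenate([s.X for s in sets], axis=0)
    y = np.concatenate([s.y for s in sets])
    # starts lose their meaning across subjects; training never uses them
    step = sets[0].step
    starts = np.arange(X.shape[0], dtype=np.int64) * step
    return SnippetSet(X, y, starts, step, sets[0].signals, sets[0].snippet_len,
                      sets[0].fs)


def _run_fold(
    train_preps: list[_PreparedSubject],
    test_prep: _PreparedSubject,
    approach: str,
    signal_set: tuple[str, ...],
    cfg: fusion.FusionConfig,
    tol_ms: float,
) -> EvalReport:
    train_set = _concat_snippet_sets(
        [_snippets(p, signal_set, "train") for p in train_preps]
    )
    test_set = _snippets(test_prep, signal_set, "test")

    members = (
        ("early", "signal_late", "sensor_late") if approach == "hybrid"
        else (approach,)
    )
    votes = []
    for member in members:
        mcfg = fusion.FusionConfig(
            approach=member, n_filters=cfg.n_filters, kernel=cfg.kernel,
            dropout=cfg.dropout, pool=cfg.pool, lr=cfg.lr, epochs=cfg.epochs,
            batch_size=cfg.batch_size, threshold=cfg.threshold,
            class_weight=cfg.class_weight, calibrate=cfg.calibrate,
            seed=cfg.seed,
        )
        model = fusion.build_model(mcfg, len(signal_set))
        model = fusion.train(model, train_set, mcfg)
        votes.append(fusion.predict_labels(model, test_set))
    if approach == "hybrid":
        labels = fusion.hybrid_vote(fusion.VoteMatrix(np.stack(votes), members))
    else:
        labels = votes[0]

    detected = labels_to_beats(
        labels, test_set.starts, test_set.step,
        approach=approach, signals=signal_set,
    )
    return evaluate_detection(detected, test_prep.reference, tol_ms)


def loso_evaluate(
    recordings: list[Recording],
    grid: list[tuple[str, tuple[str, ...]]] | None = None,
    cfg: fusion.FusionConfig | None = None,
    tol_ms: float = 50.0,
) -> pd.DataFrame:
    """Leave-one-subject-out evaluation over an approaches x signal-sets grid.

    One fold per subject: that subject's recordings are the test set and all
    other subjects' recordings the training set; per-fold P values are then
    averaged per (approach, signals, scenario) cell.  Subjects missing a
    modality required by a grid cell are skipped for that cell with a logged
    warning.  Returns a tidy frame with one row per
    (approach, signals, scenario, fold).
    """
    if grid is None:
        grid = [("hybrid", ("ecg", "ppg"))]
    cfg = cfg or fusion.FusionConfig()
    subjects = sorted({r.subject_id for r in recordings})
    if len(subjects) < 2:
        raise SignalError("LOSO needs at least 2 subjects")

    prepared: dict[tuple[str, str], _PreparedSubject] = {}
    for rec in recordings:
        prepared[(rec.subject_id, rec.scenario)] = _prepare(rec)

    rows = []
    for approach, signal_set in grid:
        signal_set = tuple(signal_set)
        for test_subject in subjects:
            test_keys = [k for k in prepared if k[0] == test_subject]
            train_keys = [k for k in prepared if k[0] != test_subject]
            usable_train = [
                prepared[k] for k in train_keys
                if all(s in prepared[k].conditioned for s in signal_set)
            ]
            for key in test_keys:
                prep = prepared[key]
                if not all(s in prep.conditioned for s in signal_set):
                    logger.warning(
                        "fold skipped: subject %s scenario %s lacks a modality "
                        "for %s", prep.subject_id, prep.scenario, signal_set,
                    )
                    continue
                report = _run_fold(
                    usable_train, prep, approach, signal_set, cfg, tol_ms
                )
                rows.append(
                    {
                        "approach": approach,
                        "signals": "+".join(signal_set),
                        "scenario": prep.scenario,
                        "fold": prep.subject_id,
                        "TP": report.TP,
                        "FP": report.FP,
                        "FN": report.FN,
                        "PPV": report.PPV,
                        "S": report.S,
                        "P": report.P,
                    }
                )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean P per (approach, signals, scenario) cell, plus a Mean_P column."""
    cell = (
        results.groupby(["approach", "signals", "scenario"])["P"]
        .mean()
        .unstack("scenario")
    )
    cell["Mean_P"] = cell.mean(axis=1)
    return cell
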