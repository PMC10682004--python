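"""Reading/writing the deposited dataset's file dialect.

The study data ships as per-signal CSV files (reference ECG, steering-wheel
ECG, PPG; one counter column plus one value column) and MAT v5 files holding
the per-frame RGB traces of the cheek face segment.  Every sample carries the
acquisition system's shared ascending counter, which is what synchronizes
modalities recorded at different rates: counters are interpreted on the
master 500 Hz clock, so the 10 Hz video trace holds every 50th counter value.

The simulator writes this same dialect, making simulated and deposited data
interchangeable downstream.  Column and variable names default to this
package's conventions but are configurable through :class:`DatasetLayout`,
since the deposited files' exact headers may differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from .types import Channel, Recording, SignalError

__all__ = [
    "DatasetLayout",
    "read_signal_csv",
    "write_signal_csv",
    "read_cheek_mat",
    "write_cheek_mat",
    "align_by_counter",
    "write_recording",
    "read_recording",
]

_CSV_MODALITIES = ("ecg_ref", "ecg_wheel", "ppg")


@dataclass(frozen=True)
class DatasetLayout:
    """Naming conventions of a dataset tree.

    ``root/<subject_id>/<scenario>/`` holds one CSV per contact signal and
    one MAT file for the cheek RGB traces.  ``fs`` maps modality tags to
    sampling rates (the paper's sensors: 500 Hz ECG/PPG, 10 Hz video).
    """

    counter_column: str = "counter"
    value_columns: dict[str, str] = field(
        default_factory=lambda: {m: m for m in _CSV_MODALITIES}
    )
    csv_names: dict[str, str] = field(
        default_factory=lambda: {m: f"{m}.csv" for m in _CSV_MODALITIES}
    )
    mat_name: str = "cheek.mat"
    mat_vars: dict[str, str] = field(
        default_factory=lambda: {"R": "R", "G": "G", "B": "B"}
    )
    mat_counter_var: str = "counter"
    fs: dict[str, float] = field(
        default_factory=lambda: {
            "ecg_ref": 500.0,
            "ecg_wheel": 500.0,
            "ppg": 500.0,
            "ippg_green": 10.0,
        }
    )


def read_signal_csv(
    path: str | Path,
    modality: str,
    layout: DatasetLayout | None = None,
) -> Channel:
    """Read one contact-sensor CSV (counter column + value column)."""
    layout = layout or DatasetLayout()
    if modality not in layout.value_columns:
        raise SignalError(f"unknown CSV modality tag {modality!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    ccol = layout.counter_column
    vcol = layout.value_columns[modality]
    for col in (ccol, vcol):
        if col not in df.columns:
            raise SignalError(f"{path.name}: missing column {col!r}")
    counter = df[ccol].to_numpy(dtype=np.int64)
    if counter.size >= 2:
        diffs = np.diff(counter)
        bad = np.flatnonzero(diffs <= 0)
        if bad.size:
            raise SignalError(
                f"{path.name}: counter not strictly increasing at row "
                f"{int(bad[0]) + 2} (1-based, after header)"
            )
        gaps = np.flatnonzero(diffs != diffs[0])
        if gaps.size:
            raise SignalError(
                f"{path.name}: counter gap at row {int(gaps[0]) + 2} "
                f"(expected stride {int(diffs[0])}, got {int(diffs[gaps[0]])})"
            )
    return Channel(df[vcol].to_numpy(dtype=float), layout.fs[modality],
                   modality, counter)


def write_signal_csv(
    ch: Channel, path: str | Path, layout: DatasetLayout | None = None,
    decimals: int = 6,
) -> Path:
    """Write one contact-sensor channel in the CSV dialect."""
    layout = layout or DatasetLayout()
    if ch.modality not in layout.value_columns:
        raise SignalError(f"modality {ch.modality!r} has no CSV dialect")
    if ch.counter is None:
        raise SignalError("CSV dialect requires a counter")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            layout.counter_column: ch.counter,
            layout.value_columns[ch.modality]: np.round(ch.samples, decimals),
        }
    )
    df.to_csv(path, index=False, float_format=f"%.{decimals}f")
    return path


def read_cheek_mat(
    path: str | Path,
    channel: str = "G",
    layout: DatasetLayout | None = None,
) -> Channel:
    """Read one colour channel of the cheek-segment trace from a MAT v5 file.

    The green channel (``channel='G'``) is the iPPG trace proper and is
    tagged ``ippg_green``; R and B are returned under the same tag for
    inspection but carry no pulse model of their own.
    """
    layout = layout or DatasetLayout()
    if channel not in layout.mat_vars:
        raise SignalError(f"channel must be one of {tuple(layout.mat_vars)}")
    mat = loadmat(str(path))
    var = layout.mat_vars[channel]
    if var not in mat:
        raise SignalError(f"{Path(path).name}: MAT variable {var!r} absent")
    samples = np.asarray(mat[var], dtype=float).ravel()
    counter = None
    if layout.mat_counter_var in mat:
        counter = np.asarray(mat[layout.mat_counter_var], dtype=np.int64).ravel()
    return Channel(samples, layout.fs["ippg_green"], "ippg_green", counter)


def write_cheek_mat(
    channels: dict[str, Channel] | Channel,
    path: str | Path,
    layout: DatasetLayout | None = None,
) -> Path:
    """Write cheek RGB traces (or a lone green trace) as a MAT v5 file."""
    layout = layout or DatasetLayout()
    if isinstance(channels, Channel):
        channels = {"G": channels}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload: dict[str, np.ndarray] = {}
    counter = None
    for color, ch in channels.items():
        payload[layout.mat_vars[color]] = ch.samples
        if ch.counter is not None:
            counter = ch.counter
    if counter is not None:
        payload[layout.mat_counter_var] = counter
    savemat(str(path), payload)
    return path


def align_by_counter(
    channels: Iterable[Channel],
    subject_id: str = "unknown",
    scenario: str = "city",
    truth=None,
) -> Recording:
    """Trim channels to their maximal common counter range.

    Each channel keeps exactly the samples whose counter falls inside the
    intersection ``[max(first counters), min(last counters)]``; after
    trimming, samples with equal counters across channels are simultaneous.
    """
    channels = list(channels)
    if not channels or any(ch.counter is None for ch in channels):
        raise SignalError("alignment requires channels with counters")
    lo = max(int(ch.counter[0]) for ch in channels)
    hi = min(int(ch.counter[-1]) for ch in channels)
    if lo > hi:
        raise SignalError("counter ranges have empty intersection")
    trimmed: dict[str, Channel] = {}
    for ch in channels:
        keep = (ch.counter >= lo) & (ch.counter <= hi)
        if not keep.any():
            raise SignalError(
                f"channel {ch.modality} has no samples in the common range"
            )
        trimmed[ch.modality] = Channel(
            ch.samples[keep], ch.fs, ch.modality, ch.counter[keep]
        )
    return Recording(subject_id, scenario, trimmed, truth)


def write_recording(
    rec: Recording, root: str | Path, layout: DatasetLayout | None = None
) -> Path:
    """Write a recording as the dataset dialect under ``root/subject/scenario``."""
    layout = layout or DatasetLayout()
    out = Path(root) / rec.subject_id / rec.scenario
    out.mkdir(parents=True, exist_ok=True)
    for modality in _CSV_MODALITIES:
        if modality in rec.channels:
            write_signal_csv(rec[modality], out / layout.csv_names[modality],
                             layout)
    if "ippg_green" in rec.channels:
        write_cheek_mat(rec["ippg_green"], out / layout.mat_name, layout)
    if rec.truth is not None:
        pd.DataFrame(
            {
                "sample_index_500hz": rec.truth.to_samples(500.0),
                "beat_time_s": rec.truth.beat_times,
            }
        ).to_csv(out / "beats.csv", index=False)
    return out


def read_recording(
    root: str | Path,
    subject_id: str,
    scenario: str,
    layout: DatasetLayout | None = None,
) -> Recording:
    """Read one subject/scenario directory written in the dataset dialect."""
    from .types import BeatTrain

    layout = layout or DatasetLayout()
    base = Path(root) / subject_id / scenario
    channels: list[Channel] = []
    for modality in _CSV_MODALITIES:
        p = base / layout.csv_names[modality]
        if p.exists():
            channels.append(read_signal_csv(p, modality, layout))
    mat = base / layout.mat_name
    if mat.exists():
        channels.append(read_cheek_mat(mat, "G", layout))
    if not channels:
        raise SignalError(f"no channels found under {base}")
    truth = None
    beats = base / "beats.csv"
    if beats.exists():
        truth = BeatTrain(pd.read_csv(beats)["beat_time_s"].to_numpy())
    return align_by_counter(channels, subject_id, scenario, truth)
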