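"""Reading CHB-MIT-style EEG records and seizure annotations.

The on-disk convention mirrors the CHB-MIT scalp EEG corpus: one EDF file per
recording (23 channels at 256 Hz is the common case) and a plain-text summary
file per patient listing, for each EDF, the number of seizures and each
seizure's start/end second.  A patient-inclusion filter drops subjects with
more than 10 seizure onsets inside any 24-hour window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import edf

Interval = tuple[float, float]

HOURS_24 = 86400.0


@dataclass
class EEGRecord:
    """One recording: multichannel signal in microvolts plus sampling metadata.

    ``start_time_s`` places the file on a shared per-patient timeline so that
    seizure times from different files of the same subject are comparable.
    """
    patient_id: str
    channel_names: list[str]
    fs: float
    samples: np.ndarray  # channels x n_samples
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x n_samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length does not match samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class SeizureAnnotation:
    """Ordered, non-overlapping seizure intervals in seconds on the patient timeline."""
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(a), float(b)) for a, b in self.intervals]
        for a, b in ivs:
            if b <= a:
                raise ValueError(f"seizure interval ({a}, {b}) has end <= start")
        ivs.sort()
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError("seizure intervals overlap")
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def onsets(self) -> list[float]:
        return [a for a, _ in self.intervals]


def read_edf(path: str | Path, patient_id: str | None = None,
             start_time_s: float = 0.0) -> EEGRecord:
    """Read an EDF/EDF+ file into an :class:`EEGRecord` (physical units)."""
    path = Path(path)
    raw = edf.read_edf_raw(path)
    pid = patient_id if patient_id is not None else path.stem.split("_")[0]
    return EEGRecord(patient_id=pid, channel_names=raw.channel_names,
                     fs=raw.fs, samples=raw.samples, start_time_s=start_time_s)


_FILE_RE = re.compile(r"^File Name:\s*(\S+)")
_COUNT_RE = re.compile(r"^Number of Seizures in File:\s*(\d+)")
_START_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([\d.]+)\s*sec")
_END_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*([\d.]+)\s*sec")


def parse_summary(path: str | Path) -> dict[str, list[Interval]]:
    """Parse a CHB-MIT-dialect summary file.

    Returns a mapping from EDF filename to the raw (unmerged) seizure
    intervals declared for that file, in file order.  Raises ``ValueError``
    when the declared seizure count disagrees with the number of start/end
    pairs present, or when an interval has end <= start.
    """
    text = Path(path).read_text()
    result: dict[str, list[Interval]] = {}
    current: str | None = None
    declared: dict[str, int] = {}
    starts: list[float] = []
    ends: list[float] = []

    def flush() -> None:
        nonlocal starts, ends
        if current is None:
            return
        if len(starts) != len(ends):
            raise ValueError(f"{current}: unpaired seizure start/end times")
        intervals = list(zip(starts, ends))
        for a, b in intervals:
            if b <= a:
                raise ValueError(f"{current}: seizure interval ({a}, {b}) has end <= start")
        if current in declared and declared[current] != len(intervals):
            raise ValueError(
                f"{current}: declared {declared[current]} seizures but found {len(intervals)}")
        result[current] = intervals
        starts, ends = [], []

    for line in text.splitlines():
        line = line.strip()
        if m := _FILE_RE.match(line):
            flush()
            current = m.group(1)
        elif m := _COUNT_RE.match(line):
            if current is None:
                raise ValueError(f"{path}: seizure count before any 'File Name:' line")
            declared[current] = int(m.group(1))
        elif m := _START_RE.match(line):
            starts.append(float(m.group(1)))
        elif m := _END_RE.match(line):
            ends.append(float(m.group(1)))
    flush()
    return result


def assemble_timeline(file_order: Sequence[str],
                      durations_s: Mapping[str, float],
                      per_file_intervals: Mapping[str, Sequence[Interval]],
                      gaps_s: Mapping[str, float] | None = None) -> SeizureAnnotation:
    """Place per-file seizure times on one absolute per-patient timeline.

    Files are laid out in ``file_order``; the offset of each file is the sum
    of the preceding durations plus any recorded gap before it (``gaps_s``,
    filename -> seconds of dead time before that file; contiguity is assumed
    where absent).
    """
    offset = 0.0
    placed: list[Interval] = []
    for name in file_order:
        if gaps_s:
            offset += float(gaps_s.get(name, 0.0))
        for a, b in per_file_intervals.get(name, ()):
            placed.append((offset + a, offset + b))
        offset += float(durations_s[name])
    return SeizureAnnotation(intervals=placed)


def max_onsets_in_24h(onsets: Iterable[float]) -> int:
    """Largest number of seizure onsets inside any 24-hour window.

    Evaluating windows anchored at each onset ([t, t + 24 h], closed) attains
    the sliding-window maximum.
    """
    times = sorted(onsets)
    best = 0
    for i, t in enumerate(times):
        count = sum(1 for u in times[i:] if u <= t + HOURS_24)
        best = max(best, count)
    return best


def filter_patients(per_patient: Mapping[str, SeizureAnnotation],
                    max_seizures_per_24h: int = 10) -> set[str]:
    """Apply the inclusion rule: keep patients with at most ``max`` onsets
    in every 24-hour window.  Counts are over the (already merged) annotation
    passed in."""
    included: set[str] = set()
    for patient, ann in per_patient.items():
        if max_onsets_in_24h(ann.onsets()) <= max_seizures_per_24h:
            included.add(patient)
    return included
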