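"""Synthetic CHB-MIT-like EEG with planted seizures.

The generator produces what the downstream pipeline expects from the real
corpus — 23-channel, 256 Hz records with a 1/f^beta "pink" background and
higher-amplitude rhythmic ictal bursts — and writes them as EDF plus
summary-text fixture pairs, so the whole detection pipeline is exercisable
without downloading any data.

Stated world
------------
* background: Gaussian noise shaped to 1/f^beta in the frequency domain
  (beta = 1 by default), RMS 30 uV per channel — a typical scalp amplitude;
* seizures: a burst of 2-3 random-phase sinusoids inside ``ictal_band_hz``
  (3-7 Hz by default, the delta/theta rhythm ictal discharges concentrate
  in), amplitude ``ictal_gain`` x the background RMS, shaped by a Hann
  envelope and shared across channels with per-channel gain in [0.5, 1.5];
* EDF encoding: 16-bit with a +-500 uV physical range.

Fixtures are deterministic: the same (config, patient_index) yields
bit-identical samples and annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import edf
from .eeg_io import EEGRecord, SeizureAnnotation


@dataclass
class SyntheticConfig:
    n_patients: int = 4
    channels: int = 23
    fs: float = 256.0
    record_duration_s: float = 1800.0
    seizures_per_patient: int = 2
    seizure_duration_s: tuple[float, float] = (60.0, 120.0)
    ictal_band_hz: tuple[float, float] = (3.0, 7.0)
    ictal_gain: float = 3.0
    noise_exponent: float = 1.0
    background_rms_uv: float = 30.0
    min_separation_s: float = 300.0
    phys_range_uv: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.ictal_gain <= 1:
            raise ValueError("ictal_gain must exceed 1 (bursts must stand out)")
        if self.seizure_duration_s[0] > self.seizure_duration_s[1]:
            raise ValueError("seizure_duration_s must be (min, max)")
        if self.ictal_band_hz[1] >= self.fs / 2:
            raise ValueError("ictal band must lie below Nyquist")


def _pink_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^beta power spectrum, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    shaping[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * shaping, n=n)
    return shaped / shaped.std()


def _place_seizures(cfg: SyntheticConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    k = cfg.seizures_per_patient
    if k == 0:
        return []
    durations = rng.uniform(*cfg.seizure_duration_s, size=k)
    sep = cfg.min_separation_s
    needed = durations.sum() + (k + 1) * sep  # separations between and margins at both ends
    free = cfg.record_duration_s - needed
    if free < 0:
        raise ValueError(
            f"cannot fit {k} seizures totalling {durations.sum():.0f}s plus {sep:.0f}s "
            f"separations into a {cfg.record_duration_s:.0f}s record")
    slack = rng.random(k + 1)
    slack = slack / slack.sum() * free
    intervals = []
    t = sep + slack[0]
    for i in range(k):
        # whole-second endpoints, matching the annotation convention
        a = float(np.floor(t))
        b = float(np.ceil(t + durations[i]))
        intervals.append((a, b))
        t += durations[i] + sep + slack[i + 1]
    return intervals


def generate_record(config: SyntheticConfig, patient_index: int) -> tuple[EEGRecord, SeizureAnnotation]:
    """Generate one patient's record with planted ictal intervals.

    Deterministic in (config.seed, patient_index); the annotation lists
    exactly the planted intervals and bursts are separated by at least
    ``min_separation_s`` so interictal windows always exist between them.
    """
    if patient_index >= config.n_patients:
        raise ValueError(f"patient_index {patient_index} >= n_patients {config.n_patients}")
    rng = np.random.default_rng([config.seed, patient_index])
    n = int(round(config.record_duration_s * config.fs))
    sig = np.empty((config.channels, n))
    for c in range(config.channels):
        sig[c] = config.background_rms_uv * _pink_noise(n, config.noise_exponent, rng)

    intervals = _place_seizures(config, rng)
    t = np.arange(n) / config.fs
    for (a, b) in intervals:
        i0, i1 = int(round(a * config.fs)), int(round(b * config.fs))
        seg_t = t[i0:i1]
        n_osc = rng.integers(2, 4)
        freqs = rng.uniform(*config.ictal_band_hz, size=n_osc)
        phases = rng.uniform(0, 2 * np.pi, size=n_osc)
        burst = np.zeros(i1 - i0)
        for f, p in zip(freqs, phases):
            burst += np.sin(2 * np.pi * f * seg_t + p)
        burst /= np.sqrt(n_osc / 2.0)  # unit RMS before the envelope
        envelope = np.hanning(i1 - i0)
        burst *= envelope * config.ictal_gain * config.background_rms_uv
        gains = rng.uniform(0.5, 1.5, size=config.channels)
        sig[:, i0:i1] += gains[:, None] * burst[None, :]

    record = EEGRecord(patient_id=f"pt{patient_index:02d}",
                       channel_names=[f"CH{i + 1:02d}" for i in range(config.channels)],
                       fs=config.fs, samples=sig)
    return record, SeizureAnnotation(intervals=intervals)


def write_fixture(record: EEGRecord, annotation: SeizureAnnotation,
                  directory: str | Path,
                  phys_range_uv: float = 500.0) -> dict[str, Path]:
    """Write one record as an EDF + CHB-MIT-dialect summary pair.

    Returns ``{"edf": ..., "summary": ...}``.  Round-tripping the EDF through
    :func:`ictalnet.eeg_io.read_edf` reproduces the signal to within one
    16-bit quantization step of the +-``phys_range_uv`` range.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    edf_name = f"{record.patient_id}_01.edf"
    edf_path = directory / edf_name
    edf.write_edf(edf_path, record.samples, record.fs,
                  channel_names=record.channel_names,
                  phys_min=-phys_range_uv, phys_max=phys_range_uv,
                  patient_id=record.patient_id)
    lines = [
        f"Data Sampling Rate: {record.fs:g} Hz",
        "",
        f"File Name: {edf_name}",
        f"Number of Seizures in File: {len(annotation)}",
    ]
    for i, (a, b) in enumerate(annotation, start=1):
        lines.append(f"Seizure {i} Start Time: {a:g} seconds")
        lines.append(f"Seizure {i} End Time: {b:g} seconds")
    lines.append("")
    summary_path = directory / f"{record.patient_id}-summary.txt"
    summary_path.write_text("\n".join(lines))
    return {"edf": edf_path, "summary": summary_path}
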