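"""Minimal EDF (European Data Format) reader and writer.

Implements exactly the subset scalp-EEG archives in the CHB-MIT style use:
16-bit integer samples, one-second data records, identical sampling rate and
physical range on every channel.  The header is the standard 256-byte fixed
block followed by 256 bytes per signal; samples are little-endian int16,
record-major with channels contiguous inside each record.

Physical values are mapped linearly between (phys_min, phys_max) and
(dig_min, dig_max), so one digital step corresponds to
(phys_max - phys_min) / (dig_max - dig_min) physical units — the quantization
granularity a round trip is bounded by.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

DIG_MIN, DIG_MAX = -32768, 32767


@dataclass
class EdfSignalData:
    """Raw contents of one EDF file: per-channel physical samples."""
    channel_names: list[str]
    fs: float
    samples: np.ndarray  # channels x n_samples, physical units
    phys_min: float
    phys_max: float


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    s = f"{value:.10g}"[:width]
    return s.ljust(width).encode("ascii")


def quantization_step(phys_min: float, phys_max: float) -> float:
    return (phys_max - phys_min) / (DIG_MAX - DIG_MIN)


def write_edf(path: str | os.PathLike, samples: np.ndarray, fs: float,
              channel_names: list[str] | None = None,
              phys_min: float = -500.0, phys_max: float = 500.0,
              patient_id: str = "X", recording_id: str = "synthetic") -> None:
    """Write a channels x n_samples array of physical values as 16-bit EDF.

    Raises ``ValueError`` if any sample exceeds the declared physical range or
    the signal length is not a whole number of one-second records.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2:
        raise ValueError("samples must be channels x n_samples")
    n_ch, n_samp = samples.shape
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("integer sampling rates only (one-second data records)")
    if n_samp % spr:
        raise ValueError(f"signal length {n_samp} is not a whole number of 1 s records at fs={fs}")
    if samples.min() < phys_min or samples.max() > phys_max:
        raise ValueError(
            f"samples span [{samples.min():.1f}, {samples.max():.1f}] uV, outside the "
            f"declared physical range [{phys_min}, {phys_max}]")
    n_rec = n_samp // spr
    if channel_names is None:
        channel_names = [f"CH{i + 1:02d}" for i in range(n_ch)]

    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (n_ch + 1)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    per_signal = b"".join([
        b"".join(_field(name, 16) for name in channel_names),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_num(phys_min, 8) for _ in range(n_ch)),
        b"".join(_num(phys_max, 8) for _ in range(n_ch)),
        b"".join(_num(DIG_MIN, 8) for _ in range(n_ch)),
        b"".join(_num(DIG_MAX, 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(str(spr), 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ])
    scale = (DIG_MAX - DIG_MIN) / (phys_max - phys_min)
    digital = np.rint((samples - phys_min) * scale + DIG_MIN)
    digital = np.clip(digital, DIG_MIN, DIG_MAX).astype("<i2")
    # record-major: for each 1 s record, all channels back to back
    records = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(records.tobytes())


def read_edf_raw(path: str | os.PathLike) -> EdfSignalData:
    """Parse an EDF file written by :func:`write_edf` (homogeneous signals).

    Errors on malformed headers, truncated data regions, zero channels, and
    per-channel sample-rate disagreement.
    """
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            n_rec = int(fixed[236:244].decode("ascii").strip())
            rec_dur = float(fixed[244:252].decode("ascii").strip())
            n_ch = int(fixed[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed EDF header ({exc})") from exc
        if n_ch <= 0:
            raise ValueError(f"{path}: EDF declares {n_ch} signals")
        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise ValueError(f"{path}: truncated EDF signal header")

        def col(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [sig[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                    for i in range(n_ch)]

        labels = [sig[i * 16:(i + 1) * 16].decode("ascii").strip() for i in range(n_ch)]
        phys_min = [float(v) for v in col(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in col(16 + 80 + 8 + 8, 8)]
        dig_min = [int(v) for v in col(16 + 80 + 8 + 16, 8)]
        dig_max = [int(v) for v in col(16 + 80 + 8 + 24, 8)]
        spr = [int(v) for v in col(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError(f"{path}: inconsistent per-channel samples per record {set(spr)}")
        raw = fh.read()
    expected = 2 * n_rec * n_ch * spr[0]
    if len(raw) < expected:
        raise ValueError(
            f"{path}: truncated data region, header promises {expected} bytes, found {len(raw)}")
    digital = np.frombuffer(raw[:expected], dtype="<i2")
    digital = digital.reshape(n_rec, n_ch, spr[0]).transpose(1, 0, 2)
    digital = digital.reshape(n_ch, n_rec * spr[0]).astype(np.float64)
    samples = np.empty_like(digital)
    for i in range(n_ch):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        samples[i] = (digital[i] - dig_min[i]) * gain + phys_min[i]
    fs = spr[0] / rec_dur
    return EdfSignalData(channel_names=labels, fs=fs, samples=samples,
                         phys_min=phys_min[0], phys_max=phys_max[0])
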