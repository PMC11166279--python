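"""From raw EDF + annotations to labeled 30 s spectrogram windows.

Reads a synthetic fixture back from disk, applies the labeling rules (merge
close seizures, keep interictal time outside a buffer around every seizure),
tiles 30 s windows and extracts Gaussian-window STFT features.
"""

from pathlib import Path

from ictalnet import (SyntheticConfig, generate_record, write_fixture, read_edf,
                      parse_summary, merge_seizure_intervals, label_segments,
                      extract_windows, stft_features, StftConfig)

cfg = SyntheticConfig(n_patients=1, record_duration_s=900.0,
                      seizure_duration_s=(40.0, 60.0), min_separation_s=150.0,
                      seed=11)
record, annotation = generate_record(cfg, 0)
paths = write_fixture(record, annotation, "scratch/fixtures_pp")

record = read_edf(paths["edf"])
(intervals,) = parse_summary(paths["summary"]).values()
print(f"read {record.patient_id}: {record.samples.shape[0]} channels x "
      f"{record.samples.shape[1]} samples; {len(intervals)} annotated seizures")

# fixture-scale rules: 120 s merge gap, 60 s interictal buffer
merged = merge_seizure_intervals(intervals, gap_s=120.0)
ictal, interictal = label_segments(merged, record.duration_s, buffer_s=60.0)
windows = extract_windows(record, ictal, 1) + extract_windows(record, interictal, 0)
n_ictal = sum(w.label for w in windows)
print(f"{len(windows)} windows of 30 s: {n_ictal} ictal, {len(windows) - n_ictal} interictal")

spec = stft_features(windows[0], record.fs, StftConfig())
print(f"spectrogram per window: {spec.values.shape} (channels x 1 Hz bins x frames), "
      f"hop {spec.hop_s:.2f} s")
# (23, 129, 59): one column every 0.5 s, frequencies 0-128 Hz at 1 Hz resolution
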