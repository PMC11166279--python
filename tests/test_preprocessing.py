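"""Labeling rules, windowing, ICA and STFT against independent oracles."""

import numpy as np
import pytest
from scipy.stats import kurtosis

from ictalnet import (merge_seizure_intervals, label_segments, extract_windows,
                      ica_denoise, stft_features, LabeledWindow, StftConfig,
                      EEGRecord, record_to_windows, SeizureAnnotation)
from conftest import random_intervals


# -- merge rule ------------------------------------------------------------

def brute_force_merge(intervals, gap_s):
    """Transitive closure by repeated pairwise union until fixpoint."""
    items = [list(iv) for iv in sorted(intervals)]
    changed = True
    while changed:
        changed = False
        for i in range(len(items) - 1):
            a, b = items[i], items[i + 1]
            if b[0] - a[1] < gap_s:
                items[i] = [a[0], max(a[1], b[1])]
                del items[i + 1]
                changed = True
                break
    return [tuple(iv) for iv in items]


def test_merge_under_gap():
    assert merge_seizure_intervals([(100, 160), (1500, 1560)]) == [(100, 1560)]


def test_no_merge_at_or_over_gap():
    assert merge_seizure_intervals([(0, 60), (2000, 2060)]) == [(0, 60), (2000, 2060)]


def test_merge_matches_closure_oracle():
    rng = np.random.default_rng(11)
    for _ in range(300):
        ivs = random_intervals(rng, n_max=8, span=10000.0, max_len=600.0)
        gap = float(rng.uniform(0, 2000))
        assert merge_seizure_intervals(ivs, gap_s=gap) == brute_force_merge(ivs, gap)


def test_merge_rejects_negative_gap():
    with pytest.raises(ValueError):
        merge_seizure_intervals([(0, 1)], gap_s=-1.0)


# -- interictal buffer -----------------------------------------------------

def test_four_hour_buffer_arithmetic():
    ictal, interictal = label_segments([(10000.0, 10100.0)], 86400.0)
    assert ictal == [(10000.0, 10100.0)]
    assert interictal == [(24500.0, 86400.0)]  # 10100 + 14400; pre-seizure side empty


def test_no_seizures_all_interictal():
    ictal, interictal = label_segments([], 5000.0)
    assert ictal == []
    assert interictal == [(0.0, 5000.0)]


def test_label_segments_per_second_oracle():
    """Per-second class membership matches a brute-force classifier."""
    rng = np.random.default_rng(13)
    for _ in range(60):
        T = 20000.0
        merged = merge_seizure_intervals(random_intervals(rng, span=T), gap_s=500.0)
        buffer_s = float(rng.uniform(100, 3000))
        ictal, interictal = label_segments(merged, T, buffer_s=buffer_s)
        for t in rng.uniform(0, T, size=200):
            in_seizure = any(a <= t < b for a, b in merged)
            in_buffer = any(a - buffer_s <= t < b + buffer_s for a, b in merged)
            in_ictal = any(a <= t < b for a, b in ictal)
            in_inter = any(a <= t < b for a, b in interictal)
            assert in_ictal == in_seizure
            assert in_inter == (not in_buffer)
            assert not (in_ictal and in_inter)


# -- window tiling ---------------------------------------------------------

def _toy_record(duration_s=400.0, fs=16.0, channels=3):
    n = int(duration_s * fs)
    samples = np.arange(channels * n, dtype=float).reshape(channels, n)
    return EEGRecord("p0", [f"C{i}" for i in range(channels)], fs, samples)


def test_window_counts():
    rec = _toy_record()
    assert len(extract_windows(rec, [(0.0, 95.0)], 1)) == 3
    assert len(extract_windows(rec, [(0.0, 29.0)], 0)) == 0


def test_window_count_oracle_and_disjointness():
    rng = np.random.default_rng(17)
    rec = _toy_record(duration_s=30000.0, fs=4.0)
    for _ in range(100):
        ivs = random_intervals(rng, n_max=6, span=30000.0, max_len=400.0)
        wins = extract_windows(rec, ivs, 1)
        assert len(wins) == sum(int((b - a) // 30) for a, b in ivs)
        spans = sorted((w.start_s, w.start_s + 30.0) for w in wins)
        assert all(s1[1] <= s2[0] + 1e-9 for s1, s2 in zip(spans, spans[1:]))
        assert all(w.samples.shape == (3, 120) for w in wins)


def test_window_samples_are_the_right_slice():
    rec = _toy_record(fs=16.0)
    (w,) = extract_windows(rec, [(60.0, 95.0)], 1)
    np.testing.assert_array_equal(w.samples, rec.samples[:, 960:960 + 480])


def test_full_chain_idempotent_on_processed_annotations():
    """merge -> label -> window applied to already-merged, buffered intervals
    reproduces the same windows."""
    rec = _toy_record(duration_s=2000.0, fs=16.0)
    ann = SeizureAnnotation([(300.0, 400.0), (900.0, 1000.0)])
    wins1 = record_to_windows(rec, ann, merge_gap_s=100.0, buffer_s=50.0)
    merged = merge_seizure_intervals(list(ann), gap_s=100.0)
    wins2 = record_to_windows(rec, SeizureAnnotation(merged),
                              merge_gap_s=100.0, buffer_s=50.0)
    assert [(w.start_s, w.label) for w in wins1] == [(w.start_s, w.label) for w in wins2]


# -- ICA denoising ---------------------------------------------------------

def _gaussian_window(seed=0, channels=4, n=512):
    rng = np.random.default_rng(seed)
    return LabeledWindow("p0", 0.0, rng.standard_normal((channels, n)), 0)


def test_ica_identity_at_infinite_threshold():
    w = _gaussian_window()
    (out,) = ica_denoise([w], kurtosis_threshold=np.inf)
    np.testing.assert_allclose(out.samples, w.samples, atol=1e-6)


def test_ica_reduces_spike_kurtosis():
    rng = np.random.default_rng(3)
    n, channels = 1024, 4
    clean = rng.standard_normal((channels, n))
    spikes = np.zeros(n)
    spikes[rng.integers(0, n, size=12)] = 25.0
    mixing = rng.uniform(0.5, 1.5, size=channels)
    noisy = clean + mixing[:, None] * spikes[None, :]
    w = LabeledWindow("p0", 0.0, noisy, 0)
    (out,) = ica_denoise([w], kurtosis_threshold=5.0)
    before = np.abs(kurtosis(noisy, axis=1)).max()
    after = np.abs(kurtosis(out.samples, axis=1)).max()
    assert after < before / 2


def test_ica_gaussian_input_passes_through():
    """All-Gaussian sources have near-zero excess kurtosis, so nothing is rejected."""
    w = _gaussian_window(seed=9, n=2048)
    (out,) = ica_denoise([w], kurtosis_threshold=5.0)
    np.testing.assert_allclose(out.samples, w.samples, atol=1e-6)


# -- STFT ------------------------------------------------------------------

def direct_stft_oracle(x: np.ndarray, window: np.ndarray, hop: int) -> np.ndarray:
    """Literal windowed-DFT magnitude by explicit summation."""
    L = len(window)
    n_frames = (len(x) - L) // hop + 1
    n_bins = L // 2 + 1
    out = np.empty((n_bins, n_frames))
    for m in range(n_frames):
        seg = x[m * hop:m * hop + L] * window
        for k in range(n_bins):
            out[k, m] = abs(np.sum(seg * np.exp(-2j * np.pi * k * np.arange(L) / L)))
    return out


def test_stft_default_shape():
    w = LabeledWindow("p0", 0.0, np.zeros((23, 7680)), 0)
    spec = stft_features(w, fs=256.0)
    assert spec.values.shape == (23, 129, 59)
    assert spec.freq_resolution_hz == 1.0


def test_stft_zero_input_zero_output():
    w = LabeledWindow("p0", 0.0, np.zeros((2, 1024)), 0)
    spec = stft_features(w, fs=256.0)
    assert np.all(spec.values == 0.0)


def test_stft_pure_tone_peaks_at_10hz():
    t = np.arange(7680) / 256.0
    tone = np.sin(2 * np.pi * 10.0 * t)
    spec = stft_features(np.tile(tone, (2, 1)), fs=256.0,
                         cfg=StftConfig(log_magnitude=False))
    peak_bins = spec.values[0].argmax(axis=0)
    assert np.all(peak_bins == 10)  # 1 Hz resolution -> bin 10


def test_stft_matches_direct_summation():
    rng = np.random.default_rng(21)
    x = rng.standard_normal(1500)
    cfg = StftConfig(window_len=128, hop=64, log_magnitude=False)
    spec = stft_features(x[None, :], fs=256.0, cfg=cfg)
    expected = direct_stft_oracle(x, cfg.window(), cfg.hop)
    assert spec.values[0].shape == expected.shape
    np.testing.assert_allclose(spec.values[0], expected, atol=1e-8)


def test_stft_nonnegative_and_crop():
    rng = np.random.default_rng(22)
    x = rng.standard_normal((3, 2048))
    spec = stft_features(x, fs=256.0, cfg=StftConfig(freq_crop_hz=(0.0, 40.0)))
    assert spec.values.min() >= 0.0
    assert spec.values.shape[1] == 41
    assert spec.freqs_hz.max() <= 40.0


def test_stft_window_longer_than_signal_errors():
    with pytest.raises(ValueError, match="window_len"):
        stft_features(np.zeros((1, 100)), fs=256.0, cfg=StftConfig(window_len=128, hop=64))
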