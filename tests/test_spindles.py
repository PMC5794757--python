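"""Sigma filter contract, threshold estimation, and spindle detection."""

import numpy as np
import pytest

from rockpsg.core import AnalysisWindow, EpochedHypnogram
from rockpsg.spindles import (
    SpindleThresholds,
    detect_spindles,
    estimate_thresholds,
    rectified_envelope,
    sigma_filter,
    spindle_counts,
)

FS = 128.0


def steady_amplitude(y, fs, skip_s=2.0):
    """Peak amplitude of the filtered steady state (edges trimmed)."""
    m = int(skip_s * fs)
    return np.abs(y[m:-m]).max()


def make_tone(freq, amp=1.0, dur=20.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


# ------------------------------------------------------------------- filter

def test_sigma_filter_passband_and_stopband():
    y_pass = sigma_filter(make_tone(13.5), FS)
    assert steady_amplitude(y_pass, FS) >= 0.95
    y_stop = sigma_filter(make_tone(5.0), FS)
    assert steady_amplitude(y_stop, FS) <= 0.05
    assert np.allclose(sigma_filter(np.zeros(1000), FS), 0.0)


def test_sigma_filter_low_rate_rejected():
    with pytest.raises(ValueError):
        sigma_filter(np.zeros(100), 32.0)


# --------------------------------------------------------------- thresholds

def test_threshold_multipliers_from_constant_amplitude():
    # a 13.5 Hz tone has a known mean rectified amplitude of 2a/pi
    x = sigma_filter(make_tone(13.5, amp=10.0, dur=60.0), FS)
    h = EpochedHypnogram(stages=["N2"] * 3)
    thr = estimate_thresholds(x, h, FS)
    assert thr.lower == pytest.approx(2 * thr.mean_rectified_amplitude)
    assert thr.upper == pytest.approx(6 * thr.mean_rectified_amplitude)
    assert thr.upper == pytest.approx(3 * thr.lower)
    assert thr.mean_rectified_amplitude == pytest.approx(2 * 10.0 / np.pi, rel=0.02)


def test_thresholds_require_eligible_epochs():
    h = EpochedHypnogram(stages=["N2"] * 2, artifact_flags=[True, True])
    with pytest.raises(ValueError):
        estimate_thresholds(np.ones(int(2 * 20 * FS)), h, FS)


def test_threshold_mean_is_masked_mean(rng):
    x = rng.standard_normal(int(4 * 20 * FS))
    stages = ["N2", "W", "N3", "REM"]
    flags = [False, False, True, False]
    h = EpochedHypnogram(stages=stages, artifact_flags=flags)
    thr = estimate_thresholds(x, h, FS)
    spe = int(20 * FS)
    manual = np.abs(x[0:spe]).mean()  # only epoch 0 is artifact-free NREM
    assert thr.mean_rectified_amplitude == pytest.approx(manual)


# ---------------------------------------------------------------- detection

def inject_burst(x, fs, onset_s, dur_s, amp, freq=13.5):
    n = int(dur_s * fs)
    t = np.arange(n) / fs
    burst = amp * np.hanning(n) * np.sin(2 * np.pi * freq * t)
    a = int(onset_s * fs)
    x[a : a + n] += burst
    return x


def clean_n2(n_epochs=3):
    return EpochedHypnogram(stages=["N2"] * n_epochs)


def test_no_upper_crossing_no_events():
    thr = SpindleThresholds.from_mean(1.0)
    x = np.full(int(60 * FS), 0.5)  # never exceeds upper=6
    assert detect_spindles(x, thr, clean_n2(), FS) == []


def test_single_burst_recovered_within_tolerance():
    # steady low-amplitude background; rectangular 13.5-Hz burst at 8x the
    # mean rectified amplitude so the threshold crossings hug the injection
    x = np.full(int(60 * FS), 1.0)
    t = np.arange(int(1.0 * FS)) / FS
    a = int(30.0 * FS)
    x[a : a + t.size] = 8.0 * np.sin(2 * np.pi * 13.5 * t + 0.3)
    h = clean_n2()
    thr = estimate_thresholds(x, h, FS)
    events = detect_spindles(x, thr, h, FS)
    assert len(events) == 1
    assert events[0].onset == pytest.approx(30.0, abs=0.1)
    assert events[0].offset == pytest.approx(31.0, abs=0.1)
    assert events[0].epoch_index == 1
    assert events[0].peak_amplitude == pytest.approx(8.0, rel=0.05)


def test_merge_rule_for_adjacent_bursts():
    h = clean_n2()
    thr = SpindleThresholds.from_mean(1.0)  # lower 2, upper 6
    fs = FS

    def burst_pair(gap_level):
        x = np.zeros(int(60 * fs))
        for onset in (10.0, 10.8):
            inject_burst(x, fs, onset, 0.5, amp=10.0)
        a, b = int(10.4 * fs), int(10.9 * fs)
        x[a:b] = gap_level  # hold the inter-burst gap at a fixed level
        return x

    merged = detect_spindles(burst_pair(3.0), thr, h, fs)  # gap above lower
    assert len(merged) == 1
    split = detect_spindles(burst_pair(0.0), thr, h, fs)  # gap below lower
    assert len(split) == 2


def test_events_outside_duration_bounds_discarded():
    h = clean_n2()
    thr = SpindleThresholds.from_mean(1.0)
    x = np.zeros(int(60 * FS))
    x[int(10 * FS) : int(10.1 * FS)] = 10.0  # 0.1 s, too short
    x[int(20 * FS) : int(24 * FS)] = 10.0  # 4 s, too long
    assert detect_spindles(x, thr, h, FS) == []


def test_detection_restricted_to_artifact_free_nrem():
    stages = ["N2", "W", "N2"]
    flags = [False, False, True]
    h = EpochedHypnogram(stages=stages, artifact_flags=flags)
    thr = SpindleThresholds.from_mean(1.0)
    x = np.zeros(int(60 * FS))
    for onset in (5.0, 25.0, 45.0):  # one per epoch
        inject_burst(x, FS, onset, 1.0, amp=20.0)
    events = detect_spindles(x, thr, h, FS)
    assert [e.epoch_index for e in events] == [0]


def test_amplitude_scaling_invariance(rng):
    x = sigma_filter(rng.standard_normal(int(60 * FS)), FS)
    inject_burst(x, FS, 15.0, 1.0, amp=8 * np.abs(x).mean())
    h = clean_n2()
    for k in (0.1, 3.7, 1000.0):
        e1 = detect_spindles(x, estimate_thresholds(x, h, FS), h, FS)
        xk = k * x
        e2 = detect_spindles(xk, estimate_thresholds(xk, h, FS), h, FS)
        assert [(e.onset, e.offset) for e in e1] == [(e.onset, e.offset) for e in e2]


def _oracle_detect(env, lower, upper, fs, bounds=(0.3, 3.0)):
    """Brute-force per-sample scan over the envelope signal."""
    events = []
    i = 0
    n = len(env)
    while i < n:
        if env[i] >= lower:
            j = i
            while j < n and env[j] >= lower:
                j += 1
            if any(env[k] >= upper for k in range(i, j)):
                dur = (j - i) / fs
                if bounds[0] <= dur <= bounds[1]:
                    events.append((i / fs, j / fs))
            i = j
        else:
            i += 1
    return events


def test_detection_matches_brute_force_oracle(rng):
    h = clean_n2()
    for trial in range(10):
        x = sigma_filter(rng.standard_normal(int(60 * FS)), FS)
        for onset in rng.uniform(2, 55, size=4):
            inject_burst(x, FS, onset, float(rng.uniform(0.4, 1.2)),
                         amp=8 * np.abs(x).mean())
        thr = estimate_thresholds(x, h, FS)
        got = [(e.onset, e.offset) for e in detect_spindles(x, thr, h, FS)]
        want = _oracle_detect(rectified_envelope(x), thr.lower, thr.upper, FS)
        assert got == pytest.approx(want)


# ------------------------------------------------------------------- counts

def test_spindle_counts_density():
    h = EpochedHypnogram(stages=["N2"] * 5 + ["W"] * 5)
    thr = SpindleThresholds.from_mean(0.1)
    x = np.zeros(int(10 * 20 * FS))
    for k in range(10):
        inject_burst(x, FS, 3.0 + 10.0 * k, 1.0, amp=10.0)  # 2 per epoch
    events = detect_spindles(x, thr, h, FS)
    count, density = spindle_counts(events, h, AnalysisWindow(0, 10))
    assert count == 10
    assert density == pytest.approx(2.0)
    count0, density0 = spindle_counts([], h, AnalysisWindow(0, 10))
    assert (count0, density0) == (0, 0.0)


def test_spindle_density_undefined_without_eligible_epochs():
    h = EpochedHypnogram(stages=["W"] * 5)
    count, density = spindle_counts([], h, AnalysisWindow(0, 5))
    assert count == 0
    assert np.isnan(density)


def test_counts_match_oracle_recount(rng):
    from conftest import random_hypnogram

    for _ in range(50):
        h = random_hypnogram(rng, 20)
        events = detect_spindles(
            _random_event_signal(rng), SpindleThresholds.from_mean(0.1), h, FS
        )
        win = AnalysisWindow(2, 15)
        count, density = spindle_counts(events, h, win)
        eligible = [
            i for i in range(2, 15)
            if h.stages[i] in {"N1", "N2", "N3"} and not h.artifact_flags[i]
        ]
        want = sum(1 for e in events if e.epoch_index in eligible)
        assert count == want
        if eligible:
            assert density == pytest.approx(want / len(eligible))
        else:
            assert np.isnan(density)


def _random_event_signal(rng):
    x = np.zeros(int(20 * 20 * FS))
    for onset in rng.uniform(0, 395, size=15):
        inject_burst(x, FS, onset, 1.0, amp=10.0)
    return x
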