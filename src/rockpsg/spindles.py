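"""Amplitude-threshold sleep-spindle detection (Ferrarelli-style).

The C3-A2 derivation is band-pass filtered in the sigma range (zero-phase,
-3 dB at 12 and 15 Hz) and rectified.  Detection thresholds derive from
the mean rectified amplitude over all artifact-free NREM samples: the
lower threshold is 2x that mean, the upper 6x.  A spindle is detected
whenever the signal amplitude exceeds the upper threshold; its extent is
widened to the surrounding lower-threshold crossings, excursions whose
lower-threshold extents touch are merged, and events outside the
configured duration bounds (0.3-3.0 s by default) are discarded.

"Signal amplitude" is the peak envelope of the rectified signal (linear
interpolation between its local maxima): the rectified trace itself
touches zero twice per sigma cycle, so thresholding it directly would
fragment every spindle into sub-cycle slivers.  Thresholds are still
*estimated* from the mean of the raw rectified signal, as specified.

Because both thresholds are proportional to the signal's own mean
amplitude, the detected event set is invariant to rescaling the input by
any positive factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .core import AnalysisWindow, EpochedHypnogram, epoch_of_time
from .spectral import NREM_STAGES

__all__ = [
    "SpindleEvent",
    "SpindleThresholds",
    "sigma_filter",
    "estimate_thresholds",
    "detect_spindles",
    "spindle_counts",
]

SIGMA_BAND = (12.0, 15.0)
DURATION_BOUNDS_S = (0.3, 3.0)


@dataclass(frozen=True)
class SpindleEvent:
    """One detected spindle; times are seconds from lights out."""

    onset: float
    offset: float
    peak_amplitude: float  # uV, rectified filtered signal
    epoch_index: int  # 20-s epoch containing the onset

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class SpindleThresholds:
    """Detection thresholds derived from the mean rectified sigma amplitude."""

    mean_rectified_amplitude: float
    lower: float  # = 2 x mean
    upper: float  # = 6 x mean

    @classmethod
    def from_mean(cls, mean: float) -> "SpindleThresholds":
        return cls(mean_rectified_amplitude=mean, lower=2.0 * mean, upper=6.0 * mean)


def _filtfilt_response(sos: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Magnitude response of forward-backward filtering (|H|^2)."""
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * freqs / fs)
    return np.abs(h) ** 2


def _realized_3db(sos, fs, grid):
    """Frequencies where the zero-phase response crosses 1/sqrt(2)."""
    mag = _filtfilt_response(sos, grid, fs)
    above = mag >= (1 / np.sqrt(2))
    edges = np.nonzero(np.diff(above.astype(int)))[0]
    pts = []
    for e in edges:
        f0, f1 = grid[e], grid[e + 1]
        m0, m1 = mag[e], mag[e + 1]
        pts.append(f0 + (1 / np.sqrt(2) - m0) / (m1 - m0) * (f1 - f0))
    return pts


@lru_cache(maxsize=None)
def _design_sigma_sos(fs: float, low: float, high: float, order: int) -> Tuple:
    """Butterworth band-pass tuned so the *zero-phase* response has its
    -3 dB points at (low, high).

    A single filtfilt pass squares the magnitude response, pulling the
    half-power points inward; the design corners are therefore widened
    iteratively until the realized -3 dB points of |H|^2 land on the
    requested band edges.
    """
    lo, hi = low, high
    grid = np.linspace(max(0.1, low - 4), min(fs / 2 - 0.1, high + 4), 8001)
    for _ in range(60):
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        pts = _realized_3db(sos, fs, grid)
        if len(pts) < 2:
            lo *= 0.99
            hi *= 1.01
            continue
        f_lo, f_hi = pts[0], pts[-1]
        err_lo, err_hi = low - f_lo, high - f_hi
        if abs(err_lo) < 1e-4 and abs(err_hi) < 1e-4:
            break
        lo += err_lo
        hi += err_hi
        if lo <= 0 or hi >= fs / 2:
            raise ValueError("sigma filter design unstable at this sampling rate")
    return tuple(map(tuple, sos))


def sigma_filter(
    x: np.ndarray,
    sampling_rate: float,
    band: Tuple[float, float] = SIGMA_BAND,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase sigma band-pass (-3 dB at 12 and 15 Hz by default).

    ``order`` is the order of the underlying Butterworth low/high pair
    (band-pass polynomial order 2x, i.e. 8th order), applied forward and
    backward.
    """
    if sampling_rate < 64:
        raise ValueError("sampling_rate must be >= 64 Hz for the sigma band")
    sos = np.asarray(_design_sigma_sos(float(sampling_rate), band[0], band[1], order))
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def rectified_envelope(filtered: np.ndarray) -> np.ndarray:
    """Peak envelope of the rectified signal.

    Linear interpolation between the local maxima of ``|filtered|``,
    tracking the instantaneous sigma amplitude without the sub-cycle
    zero dips of the raw rectified trace.
    """
    rect = np.abs(np.asarray(filtered, dtype=float))
    if rect.size < 3:
        return rect.copy()
    interior = np.nonzero(
        (rect[1:-1] >= rect[:-2]) & (rect[1:-1] >= rect[2:])
    )[0] + 1
    peaks = np.concatenate(([0], interior, [rect.size - 1]))
    return np.interp(np.arange(rect.size), peaks, rect[peaks])


def _eligible_epochs(hypnogram: EpochedHypnogram, stages=NREM_STAGES) -> np.ndarray:
    stage_arr = hypnogram.stage_array()
    art = hypnogram.artifact_array()
    return np.array([(s in stages) and not a for s, a in zip(stage_arr, art)])


def _sample_mask(eligible: np.ndarray, n_samples: int, fs: float,
                 epoch_length: float) -> np.ndarray:
    spe = int(round(epoch_length * fs))
    mask = np.zeros(n_samples, dtype=bool)
    for i in np.nonzero(eligible)[0]:
        mask[i * spe : min((i + 1) * spe, n_samples)] = True
    return mask


def estimate_thresholds(
    filtered: np.ndarray,
    hypnogram: EpochedHypnogram,
    sampling_rate: float,
) -> SpindleThresholds:
    """Thresholds from the mean rectified amplitude over artifact-free NREM.

    The mean is taken over all artifact-free NREM *samples* of the
    filtered signal (a single grand mean, not a mean of epoch means).
    """
    eligible = _eligible_epochs(hypnogram)
    mask = _sample_mask(eligible, len(filtered), sampling_rate, hypnogram.epoch_length)
    if not mask.any():
        raise ValueError("no artifact-free NREM epochs to estimate thresholds from")
    mean = float(np.abs(filtered[mask]).mean())
    return SpindleThresholds.from_mean(mean)


def detect_spindles(
    filtered: np.ndarray,
    thresholds: SpindleThresholds,
    hypnogram: EpochedHypnogram,
    sampling_rate: float,
    duration_bounds: Tuple[float, float] = DURATION_BOUNDS_S,
    merge: bool = True,
) -> List[SpindleEvent]:
    """Detect spindles in the rectified filtered signal.

    Candidate events are excursions of the rectified-signal peak envelope
    above the upper threshold; each is widened to the nearest crossings of
    the lower threshold.  With ``merge=True`` (default) excursions sharing
    a lower-threshold extent collapse into one event.  Events are kept
    only if their onset falls in an artifact-free NREM epoch and their
    duration lies within ``duration_bounds``.
    """
    rect = np.abs(np.asarray(filtered, dtype=float))
    env = rectified_envelope(filtered)
    fs = sampling_rate
    eligible = _eligible_epochs(hypnogram)

    above_lower = env >= thresholds.lower
    above_upper = env >= thresholds.upper
    if not above_upper.any():
        return []

    # Runs of the lower-threshold mask; each run containing >=1 upper
    # crossing is one (merged) candidate event.
    padded = np.concatenate(([False], above_lower, [False]))
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]  # half-open

    events: List[SpindleEvent] = []
    for a, b in zip(starts, ends):
        seg_upper = above_upper[a:b]
        if not seg_upper.any():
            continue
        if merge:
            spans = [(a, b)]
        else:
            # one event per upper excursion, each widened to the same
            # lower-threshold extent boundaries
            up = np.concatenate(([False], seg_upper, [False]))
            du = np.diff(up.astype(int))
            spans = [
                (a, b)
                for _ in np.nonzero(du == 1)[0]
            ]
        for sa, sb in spans:
            onset = sa / fs
            offset = sb / fs
            dur = offset - onset
            if not (duration_bounds[0] <= dur <= duration_bounds[1]):
                continue
            ep = epoch_of_time(onset, hypnogram.epoch_length)
            if ep >= len(eligible) or not eligible[ep]:
                continue
            events.append(
                SpindleEvent(
                    onset=onset,
                    offset=offset,
                    peak_amplitude=float(rect[sa:sb].max()),
                    epoch_index=ep,
                )
            )
    return events


def spindle_counts(
    events: List[SpindleEvent],
    hypnogram: EpochedHypnogram,
    window: AnalysisWindow,
) -> Tuple[int, float]:
    """Spindle count and density (events per 20-s epoch) within a window.

    Only events whose onset lies in an artifact-free NREM epoch inside the
    window are counted; density divides by the number of such epochs.
    Returns ``(0, nan)`` when the window contains no eligible epoch.
    """
    window = window.clip_to(hypnogram)
    eligible = _eligible_epochs(hypnogram)
    in_win = np.zeros_like(eligible)
    in_win[window.start_epoch : window.end_epoch] = True
    eligible = eligible & in_win
    n_eligible = int(eligible.sum())
    count = sum(
        1
        for e in events
        if 0 <= e.epoch_index < len(eligible) and eligible[e.epoch_index]
    )
    if n_eligible == 0:
        return count, float("nan")
    return count, count / n_eligible
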