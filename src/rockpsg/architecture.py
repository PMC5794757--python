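"""Hypnogram-derived sleep-architecture metrics.

All metrics are defined on 20-s scored epochs.  Latencies follow the
study conventions: sleep latency runs from lights out to the first
occurrence of N2; SWS and REM latencies run from sleep onset (the first
N2 epoch) to the first occurrence of N3 / REM.  Metrics whose defining
event is absent from the hypnogram (e.g. REM latency in a night without
REM) are *undefined* and returned as ``nan`` rather than zero.

Windowed quantities (stage minutes, WASO, efficiency, stage changes,
excluded epochs) are computed over half-open epoch windows relative to
lights out; see :class:`rockpsg.core.AnalysisWindow`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .core import AnalysisWindow, EpochedHypnogram

__all__ = [
    "sleep_latency",
    "n2_latency_from_n1",
    "sws_latency",
    "rem_latency",
    "stage_minutes",
    "waso",
    "sleep_efficiency",
    "stage_changes",
    "excluded_epochs",
    "stimulation_off_epoch_c1",
    "ArchitectureReport",
    "architecture_report",
]


def _epochs_to_min(n_epochs: float, epoch_length: float) -> float:
    return n_epochs * epoch_length / 60.0


def sleep_latency(h: EpochedHypnogram) -> float:
    """Minutes from lights out to the first N2 epoch; nan if no N2."""
    onset = h.sleep_onset_epoch()
    if onset is None:
        return math.nan
    return _epochs_to_min(onset, h.epoch_length)


def n2_latency_from_n1(h: EpochedHypnogram) -> float:
    """Minutes between the first N2 and the first N1 epoch.

    May be negative when N2 precedes N1; reported as-is.  nan if either
    stage never occurs.
    """
    first_n1 = h.first_epoch_of("N1")
    first_n2 = h.first_epoch_of("N2")
    if first_n1 is None or first_n2 is None:
        return math.nan
    return _epochs_to_min(first_n2 - first_n1, h.epoch_length)


def _latency_from_onset(h: EpochedHypnogram, stage: str) -> float:
    onset = h.sleep_onset_epoch()
    if onset is None:
        return math.nan
    target = h.first_epoch_of(stage, start=onset)
    if target is None:
        return math.nan
    return _epochs_to_min(target - onset, h.epoch_length)


def sws_latency(h: EpochedHypnogram) -> float:
    """Minutes from sleep onset to the first N3 epoch; nan if undefined."""
    return _latency_from_onset(h, "N3")


def rem_latency(h: EpochedHypnogram) -> float:
    """Minutes from sleep onset to the first REM epoch; nan if undefined."""
    return _latency_from_onset(h, "REM")


def _window_stages(h: EpochedHypnogram, window: AnalysisWindow) -> np.ndarray:
    arr = h.stage_array()
    if window.start_epoch >= arr.size:
        raise ValueError("window lies beyond the hypnogram")
    return arr[window.start_epoch : window.end_epoch]


def stage_minutes(h: EpochedHypnogram, window: AnalysisWindow, stage: str) -> float:
    """Minutes scored as ``stage`` within the window."""
    seg = _window_stages(h, window)
    if seg.size == 0:
        raise ValueError("empty analysis window")
    return _epochs_to_min(int((seg == stage).sum()), h.epoch_length)


def waso(h: EpochedHypnogram, window: AnalysisWindow) -> float:
    """Wake after sleep onset within the window, in minutes.

    Counts W epochs strictly after the sleep-onset epoch.  Wake before
    onset contributes to sleep latency only.  If sleep onset has not yet
    occurred, WASO is 0 by definition.
    """
    seg = _window_stages(h, window)
    if seg.size == 0:
        raise ValueError("empty analysis window")
    onset = h.sleep_onset_epoch()
    if onset is None:
        return 0.0
    start = max(onset + 1, window.start_epoch)
    arr = h.stage_array()[start : window.end_epoch]
    return _epochs_to_min(int((arr == "W").sum()), h.epoch_length)


def sleep_efficiency(h: EpochedHypnogram, window: AnalysisWindow) -> float:
    """Percentage of window epochs (after lights out) spent asleep (non-W)."""
    seg = _window_stages(h, window)
    if seg.size == 0:
        raise ValueError("empty analysis window")
    return float((seg != "W").sum()) / seg.size * 100.0


def stage_changes(h: EpochedHypnogram, window: AnalysisWindow) -> float:
    """Number of stage transitions from the sleep-onset epoch to window end.

    Counts adjacent epoch pairs with differing labels within
    ``[max(onset, window.start), window.end)``.  nan when sleep onset does
    not occur before the window end.
    """
    onset = h.sleep_onset_epoch()
    if onset is None or onset >= window.end_epoch:
        return math.nan
    start = max(onset, window.start_epoch)
    arr = h.stage_array()[start : window.end_epoch]
    if arr.size < 2:
        return 0.0
    return float((arr[1:] != arr[:-1]).sum())


def excluded_epochs(h: EpochedHypnogram, window: AnalysisWindow) -> float:
    """Artifact-flagged epochs from sleep onset to window end; nan without
    sleep onset."""
    onset = h.sleep_onset_epoch()
    if onset is None or onset >= window.end_epoch:
        return math.nan
    start = max(onset, window.start_epoch)
    flags = h.artifact_array()[start : window.end_epoch]
    return float(flags.sum())


def stimulation_off_epoch_c1(
    h: EpochedHypnogram, run_length: int = 3
) -> Optional[int]:
    """Epoch (relative to lights out) at which C1 stimulation switches off.

    The platform stops after the first occurrence of ``run_length``
    consecutive N2 epochs; the returned index is the *third* epoch of that
    run (stimulation stops at its end).  Returns ``None`` when no such run
    exists, in which case stimulation runs for the full window.
    """
    arr = h.stage_array()
    run = 0
    for i, s in enumerate(arr):
        run = run + 1 if s == "N2" else 0
        if run >= run_length:
            return i
    return None


@dataclass
class ArchitectureReport:
    """Table-1-style metrics for one recording over one analysis window."""

    sleep_latency_min: float
    n2_latency_from_n1_min: float
    sws_latency_min: float
    rem_latency_min: float
    sleep_efficiency_pct: float
    n1_min: float
    n2_min: float
    n3_min: float
    waso_min: float
    stage_changes: float
    excluded_epochs: float

    def to_series(self) -> pd.Series:
        return pd.Series(asdict(self))


def architecture_report(
    h: EpochedHypnogram, window: AnalysisWindow
) -> ArchitectureReport:
    """Compute every architecture metric over ``window``.

    Full-night latencies are reported unchanged in every window (they are
    properties of the night, not of the window), matching how the study
    tabulates them.
    """
    window = window.clip_to(h)
    return ArchitectureReport(
        sleep_latency_min=sleep_latency(h),
        n2_latency_from_n1_min=n2_latency_from_n1(h),
        sws_latency_min=sws_latency(h),
        rem_latency_min=rem_latency(h),
        sleep_efficiency_pct=sleep_efficiency(h, window),
        n1_min=stage_minutes(h, window, "N1"),
        n2_min=stage_minutes(h, window, "N2"),
        n3_min=stage_minutes(h, window, "N3"),
        waso_min=waso(h, window),
        stage_changes=stage_changes(h, window),
        excluded_epochs=excluded_epochs(h, window),
    )
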