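"""Rocking-platform trajectory model and per-night stimulation timelines.

The platform moves sinusoidally along one axis (translations x/y/z or
rotations roll/pitch).  The two selectable frequencies (0.24 Hz fast,
0.16 Hz slow) share a common peak velocity of 0.1 m/s, so the
displacement amplitude is adapted per frequency: A = v_max / (2*pi*f),
giving 0.066 m at 0.24 Hz and 0.10 m at 0.16 Hz.  "Amplitude" is peak
displacement (not peak-to-peak); that convention reproduces both
published amplitudes from the velocity constraint.  For rotational axes
the same formula is reused with the amplitude in radians and a nominal
peak tangential speed (no lever arm is modelled).

Timelines: stimulation starts at lights out.  In C1 it stops at the end
of the third epoch of the first run of three consecutive N2 epochs, with
recorded platform noise covering the remainder of the first 2 hours; in
C2 it runs for the full 2 hours; baseline nights play recorded noise for
the first 2 hours so that acoustics match.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .architecture import stimulation_off_epoch_c1
from .core import EpochedHypnogram

__all__ = [
    "TrajectorySpec",
    "StimulationTimeline",
    "amplitude_for_velocity",
    "trajectory",
    "build_timeline",
    "FAST_FREQ_HZ",
    "SLOW_FREQ_HZ",
    "PEAK_VELOCITY_MS",
    "STIM_WINDOW_S",
]

FAST_FREQ_HZ = 0.24
SLOW_FREQ_HZ = 0.16
PEAK_VELOCITY_MS = 0.1
STIM_WINDOW_S = 7200.0

_AXES = ("x", "y", "z", "roll", "pitch")


def amplitude_for_velocity(frequency: float, peak_velocity: float) -> float:
    """Displacement amplitude reaching ``peak_velocity`` at ``frequency``.

    A = v / (2*pi*f); unrounded.  Callers round for display (the platform
    specs quote 0.066 m and 0.10 m).
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    return peak_velocity / (2.0 * math.pi * frequency)


@dataclass(frozen=True)
class TrajectorySpec:
    """One axis/frequency/amplitude setting of the platform."""

    axis: str
    frequency: float  # Hz
    amplitude: float  # m (translations) or rad (rotations)

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def peak_velocity(self) -> float:
        return 2.0 * math.pi * self.frequency * self.amplitude

    @classmethod
    def velocity_matched(
        cls, axis: str, frequency: float, peak_velocity: float = PEAK_VELOCITY_MS
    ) -> "TrajectorySpec":
        return cls(axis, frequency, amplitude_for_velocity(frequency, peak_velocity))


def trajectory(spec: TrajectorySpec, t) -> Tuple[np.ndarray, np.ndarray]:
    """Position and velocity of the sinusoidal motion at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    w = 2.0 * math.pi * spec.frequency
    pos = spec.amplitude * np.sin(w * t)
    vel = spec.amplitude * w * np.cos(w * t)
    return pos, vel


@dataclass(frozen=True)
class StimulationTimeline:
    """Per-night stimulation / recorded-noise intervals (s from lights out).

    ``None`` denotes an empty interval.  For B and C1 the union of the two
    intervals covers the full 2-h window, keeping acoustics constant.
    """

    condition: str
    on_interval: Optional[Tuple[float, float]]
    noise_interval: Optional[Tuple[float, float]]


def build_timeline(
    condition: str,
    hypnogram: Optional[EpochedHypnogram] = None,
    window_s: float = STIM_WINDOW_S,
) -> StimulationTimeline:
    """Stimulation timeline for one night of the given condition.

    B: no motion, noise for the full window.  C1: motion from lights out
    until the end of the third epoch of the first 3-consecutive-N2 run
    (needs the hypnogram), then noise; if no such run occurs, stimulation
    runs the full window (with a warning) and no noise is played.  C2:
    motion for the full window.
    """
    if condition == "B":
        return StimulationTimeline("B", None, (0.0, window_s))
    if condition == "C2":
        return StimulationTimeline("C2", (0.0, window_s), None)
    if condition != "C1":
        raise ValueError(f"unknown condition {condition!r}")
    if hypnogram is None:
        raise ValueError("C1 timeline requires a hypnogram")
    off_epoch = stimulation_off_epoch_c1(hypnogram)
    if off_epoch is None:
        warnings.warn(
            "no run of 3 consecutive N2 epochs; C1 stimulation ran full window"
        )
        return StimulationTimeline("C1", (0.0, window_s), None)
    off_s = min((off_epoch + 1) * hypnogram.epoch_length, window_s)
    return StimulationTimeline("C1", (0.0, off_s), (off_s, window_s))
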