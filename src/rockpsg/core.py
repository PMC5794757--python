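"""Core containers shared across the toolkit.

Conventions used everywhere in :mod:`rockpsg`:

* time is measured in **seconds from lights out**;
* sleep is staged on fixed **20-s epochs**, indexed 0-based from the start
  of the recording;
* analysis windows are **half-open epoch ranges relative to lights out**
  (the first 2 hours after lights out is ``[0, 360)``);
* **sleep onset** is the first epoch scored N2 (the same anchor used for
  sleep latency and for switching stimulation off).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Valid sleep-stage labels (wake, NREM 1-3, REM).
STAGES = ("W", "N1", "N2", "N3", "REM")

#: Scoring epoch length in seconds.
EPOCH_LENGTH_S = 20.0


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass
class EpochedHypnogram:
    """A visually-scored stage sequence with per-epoch artifact flags.

    Parameters
    ----------
    stages
        One label per 20-s epoch, each in :data:`STAGES`.
    artifact_flags
        Boolean per epoch; flagged epochs are excluded from spectral and
        event-density analyses.  Orthogonal to the stage labels.
    lights_out_epoch
        0-based index of the first epoch after lights out.  Analysis
        windows are expressed relative to this anchor.
    epoch_length
        Epoch duration in seconds (20 s throughout).
    """

    stages: Sequence[str]
    artifact_flags: Optional[Sequence[bool]] = None
    lights_out_epoch: int = 0
    epoch_length: float = EPOCH_LENGTH_S

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        if self.stages.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"invalid stage labels: {sorted(bad)}")
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.stages.size, dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if self.artifact_flags.size != self.stages.size:
            raise ValueError("artifact_flags length must match stages")
        if not (0 <= self.lights_out_epoch < self.stages.size):
            raise ValueError("lights_out_epoch outside hypnogram")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def n_epochs_after_lights_out(self) -> int:
        return self.n_epochs - self.lights_out_epoch

    def stage_array(self) -> np.ndarray:
        """Stage labels from lights out onward."""
        return self.stages[self.lights_out_epoch:]

    def artifact_array(self) -> np.ndarray:
        """Artifact flags from lights out onward."""
        return self.artifact_flags[self.lights_out_epoch:]

    def first_epoch_of(self, stage: str, start: int = 0) -> Optional[int]:
        """Index (relative to lights out) of the first ``stage`` epoch at or
        after relative index ``start``; ``None`` if absent."""
        arr = self.stage_array()
        hits = np.nonzero(arr[start:] == stage)[0]
        if hits.size == 0:
            return None
        return int(hits[0] + start)

    def sleep_onset_epoch(self) -> Optional[int]:
        """First N2 epoch relative to lights out (sleep onset), or ``None``."""
        return self.first_epoch_of("N2")


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open epoch range ``[start_epoch, end_epoch)`` relative to
    lights out."""

    start_epoch: int
    end_epoch: int

    def __post_init__(self) -> None:
        if self.start_epoch >= self.end_epoch:
            raise ValueError("start_epoch must be < end_epoch")
        if self.start_epoch < 0:
            raise ValueError("start_epoch must be >= 0")

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch

    @classmethod
    def first_hours(cls, hours: float) -> "AnalysisWindow":
        n = hours * 3600.0 / EPOCH_LENGTH_S
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window must contain a whole number of epochs")
        return cls(0, int(round(n)))

    @classmethod
    def entire(cls, hypnogram: EpochedHypnogram) -> "AnalysisWindow":
        return cls(0, hypnogram.n_epochs_after_lights_out)

    def clip_to(self, hypnogram: EpochedHypnogram) -> "AnalysisWindow":
        end = min(self.end_epoch, hypnogram.n_epochs_after_lights_out)
        return AnalysisWindow(self.start_epoch, end)


#: The paper-style standard windows.
FIRST_2H = AnalysisWindow.first_hours(2)
FIRST_3H = AnalysisWindow.first_hours(3)


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts.

    ``samples`` is ``(n_channels, n_samples)``; sample 0 is taken to
    coincide with lights out.  ``reference`` names the common recording
    reference of all channels (``Cz`` for raw recordings, or a derivation
    label such as ``A2`` after re-referencing).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: Sequence[str]
    reference: str = "Cz"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = list(self.channel_labels)
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("one label per channel required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not present (have {self.channel_labels})"
            ) from None
        return self.samples[i]


def epoch_of_time(t_seconds: float, epoch_length: float = EPOCH_LENGTH_S) -> int:
    """20-s epoch index (relative to lights out) containing time ``t``."""
    return int(np.floor(t_seconds / epoch_length))
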