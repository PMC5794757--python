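"""Scoring of the 40-item word-pair declarative memory task.

A fully correct response earns one point, a response with a minor mistake
(plural/singular form, spelling) half a point.  Session scores therefore
live on a 0-40 scale in half-point steps; they are stored internally as
doubled integers so that no floating-point drift can ever break the
half-point granularity.

Overnight improvement is delayed minus immediate recall; the initial
acquisition rate expresses immediate recall as a percentage of delayed
recall.  Subjects who reach the 40-point ceiling in any session are
excluded from all conditions (subject-level exclusion, mirroring the
study's 18 -> 16 reduction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, List, Sequence

import pandas as pd

__all__ = [
    "MAX_POINTS",
    "WordPairSession",
    "classify_mistake",
    "score_response",
    "overnight_improvement",
    "initial_acquisition_rate",
    "apply_ceiling_exclusion",
    "sessions_to_frame",
]

MAX_POINTS = 40.0

_PLURAL_SUFFIXES = ("s", "es", "n", "en", "e", "er")


def _to_half_units(points: float) -> int:
    doubled = points * 2.0
    if abs(doubled - round(doubled)) > 1e-9:
        raise ValueError(f"score {points} is not a multiple of 0.5")
    return int(round(doubled))


@dataclass(frozen=True)
class WordPairSession:
    """One subject x condition session of the word-pair task."""

    subject: str
    condition: str
    immediate_half_units: int  # doubled points, exact
    delayed_half_units: int
    excluded: bool = False

    def __post_init__(self) -> None:
        for v in (self.immediate_half_units, self.delayed_half_units):
            if not (0 <= v <= int(MAX_POINTS * 2)):
                raise ValueError("scores must lie in [0, 40]")

    @classmethod
    def from_points(
        cls,
        subject: str,
        condition: str,
        immediate: float,
        delayed: float,
        excluded: bool = False,
    ) -> "WordPairSession":
        return cls(
            subject,
            condition,
            _to_half_units(immediate),
            _to_half_units(delayed),
            excluded,
        )

    @property
    def immediate_score(self) -> float:
        return self.immediate_half_units / 2.0

    @property
    def delayed_score(self) -> float:
        return self.delayed_half_units / 2.0


def _edit_distance_leq1(a: str, b: str) -> bool:
    if a == b:
        return True
    if abs(len(a) - len(b)) > 1:
        return False
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b)) <= 1
    if len(a) > len(b):
        a, b = b, a
    # b is one longer: check deletion of one char
    i = 0
    while i < len(a) and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


def classify_mistake(given: str, correct: str) -> str:
    """Classify a response as ``exact``, ``minor`` or ``wrong``.

    Case-insensitive exact match is exact; a pluralization-suffix
    difference or a single-character edit counts as minor (spelling /
    plural-singular form); anything else is wrong.
    """
    g = given.strip().lower()
    c = correct.strip().lower()
    if g == c:
        return "exact"
    if not g:
        return "wrong"
    for suf in _PLURAL_SUFFIXES:
        if g == c + suf or c == g + suf:
            return "minor"
    if _edit_distance_leq1(g, c):
        return "minor"
    return "wrong"


def score_response(given: str, correct: str, mistake_class: str = None) -> float:
    """Points for one response: exact 1.0, minor 0.5, wrong 0.0.

    ``mistake_class`` may be supplied directly (when responses were
    adjudicated externally); otherwise :func:`classify_mistake` is used.
    """
    cls = mistake_class if mistake_class is not None else classify_mistake(given, correct)
    if cls == "exact":
        return 1.0
    if cls == "minor":
        return 0.5
    if cls == "wrong":
        return 0.0
    raise ValueError(f"unknown mistake class {cls!r}")


def overnight_improvement(s: WordPairSession) -> float:
    """Delayed minus immediate recall, in points."""
    if s.excluded:
        raise ValueError(f"session {s.subject}/{s.condition} is excluded")
    return (s.delayed_half_units - s.immediate_half_units) / 2.0


def initial_acquisition_rate(s: WordPairSession) -> float:
    """Immediate recall as a percentage of delayed recall; nan if delayed=0."""
    if s.excluded:
        raise ValueError(f"session {s.subject}/{s.condition} is excluded")
    if s.delayed_half_units == 0:
        return math.nan
    return s.immediate_half_units / s.delayed_half_units * 100.0


def apply_ceiling_exclusion(
    sessions: Sequence[WordPairSession],
) -> List[WordPairSession]:
    """Flag every session of any subject who reaches 40 points anywhere.

    Reaching the maximum in either immediate or delayed recall of any
    night triggers subject-level exclusion (ceiling effect).
    """
    ceiling = int(MAX_POINTS * 2)
    at_ceiling = {
        s.subject
        for s in sessions
        if s.immediate_half_units >= ceiling or s.delayed_half_units >= ceiling
    }
    return [replace(s, excluded=s.subject in at_ceiling) for s in sessions]


def sessions_to_frame(sessions: Iterable[WordPairSession]) -> pd.DataFrame:
    """Tidy view: subject, condition, immediate, delayed, excluded."""
    return pd.DataFrame(
        {
            "subject": s.subject,
            "condition": s.condition,
            "immediate": s.immediate_score,
            "delayed": s.delayed_score,
            "excluded": s.excluded,
        }
        for s in sessions
    )
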