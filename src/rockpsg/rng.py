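"""Deterministic named random streams.

All randomness in the simulator flows from a single integer seed through
named sub-streams keyed by (purpose, subject, condition, ...).  Streams are
derived with a stable hash, so adding subjects or conditions to a cohort
never perturbs the draws of existing ones, and identical seeds give
bit-identical output across runs and platforms.
"""

from __future__ import annotations

import hashlib

import numpy as np


def stream_seed(seed: int, *keys) -> int:
    """Derive a child seed (< 2**31) from ``seed`` and a tuple of keys.

    Keys are folded through SHA-256 of their repr, which is stable across
    processes (unlike Python's builtin ``hash``).
    """
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for k in keys:
        h.update(b"\x1f")
        h.update(repr(k).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def stream_rng(seed: int, *keys) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the named sub-stream."""
    return np.random.default_rng(stream_seed(seed, *keys))
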