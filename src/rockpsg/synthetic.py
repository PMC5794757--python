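"""Synthetic polysomnography cohorts with known ground truth.

This module emulates the study conditions end to end: 18 subjects, three
nights each (baseline B, stimulation-until-sleep-onset C1, 2-h
stimulation C2), 8-h nights staged on 20-s epochs, EEG at 256 Hz on
Cz-referenced channels (F3, C3, A2).

Hypnograms are per-epoch Markov chains over {W, N1, N2, N3, REM}.  The
default transition matrix was calibrated once so that simulated baseline
nights reproduce the study's Table-1-scale architecture (sleep latency
about 7-8 min, sleep efficiency about 96%, N2 about 250 min, N3 about
95 min).  A homogeneous chain cannot reproduce ultradian structure, so
REM latency is far shorter than in real nights; see the methods note.

EEG is 1/f Gaussian background shaped in the frequency domain (exponent
1.0 awake/REM, 1.5 in NREM, with deeper stages given larger amplitude),
plus additively injected events whose exact positions and amplitudes are
recorded as ground truth: sleep spindles (12-15 Hz Hann-windowed bursts,
0.5-1.5 s), slow-oscillation half-wave pairs (single 0.5-1.5 Hz sine
cycles), and waking alpha.  Events are placed at random offsets within
their epoch with a minimum 0.5-s gap and no overlap, keeping ground-truth
bookkeeping unambiguous.

Condition effects are additive shifts on the N2 dwell probability and on
spindle density, applied only while stimulation is on (the full first
2 h in C2; until the first run of three consecutive N2 epochs in C1),
defaulting to the direction the study reports (more N2 and more spindles
under C2 in the stimulated window).

All randomness flows from one integer seed through named streams keyed
by (purpose, subject, condition), so identical seeds give bit-identical
cohorts and adding subjects never perturbs existing ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    EEGRecording,
    EpochedHypnogram,
    STAGES,
)
from .rng import stream_rng

__all__ = [
    "SimulationConfig",
    "ConditionEffects",
    "GroundTruth",
    "DEFAULT_TRANSITION_MATRIX",
    "generate_hypnogram",
    "synthesize_eeg",
    "generate_wordpair_data",
    "match_events",
]

#: Per-epoch stage-transition probabilities (rows/cols ordered as STAGES),
#: calibrated to baseline Table-1-scale architecture.
DEFAULT_TRANSITION_MATRIX = np.array(
    [
        # W      N1     N2     N3     REM
        [0.930, 0.062, 0.000, 0.000, 0.008],  # W
        [0.020, 0.750, 0.220, 0.000, 0.010],  # N1
        [0.001, 0.005, 0.932, 0.040, 0.022],  # N2
        [0.001, 0.000, 0.099, 0.895, 0.005],  # N3
        [0.003, 0.008, 0.052, 0.000, 0.937],  # REM
    ]
)

#: Background RMS amplitude (uV) per stage before event injection.
DEFAULT_STAGE_RMS = {"W": 10.0, "N1": 12.0, "N2": 15.0, "N3": 25.0, "REM": 10.0}

NREM = ("N1", "N2", "N3")


@dataclass
class ConditionEffects:
    """Additive shifts applied inside the stimulation window only."""

    n2_dwell_shift: float = 0.015  # added to P(next = N2)
    spindle_density_shift: float = 0.0  # added to per-epoch spindle density


@dataclass
class SimulationConfig:
    """Parameters of one simulated cohort (defaults = study conditions)."""

    n_subjects: int = 18
    conditions: Tuple[str, ...] = ("B", "C1", "C2")
    night_duration: float = 28800.0  # s (8 h)
    sampling_rate: float = 256.0  # Hz
    epoch_length: float = 20.0  # s, fixed by the scoring convention
    stage_transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION_MATRIX.copy()
    )
    spindle_density_target: float = 2.2  # events per 20-s NREM epoch
    so_density_target: float = 6.3  # half-waves per 20-s epoch
    background_exponent_wake: float = 1.0  # 1/f^beta awake and in REM
    background_exponent_nrem: float = 1.5
    stage_rms: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_RMS)
    )
    artifact_rate: float = 0.028  # ~40 flagged epochs per 1440-epoch night
    condition_effects: ConditionEffects = field(default_factory=ConditionEffects)
    stim_window_epochs: int = 360  # first 2 h
    spindle_freq_range: Tuple[float, float] = (12.5, 14.5)  # Hz
    spindle_duration_range: Tuple[float, float] = (0.5, 1.5)  # s
    spindle_amp_range: Tuple[float, float] = (20.0, 40.0)  # uV
    so_freq_range: Tuple[float, float] = (0.5, 1.5)  # Hz
    so_amp_range: Tuple[float, float] = (30.0, 75.0)  # uV, spans 37.5 criterion
    wake_alpha_amp: float = 8.0  # uV, 10-Hz tone in W epochs
    min_event_gap: float = 0.5  # s
    seed: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.stage_transition_matrix, dtype=float)
        if m.shape != (5, 5):
            raise ConfigurationError("transition matrix must be 5x5")
        if np.any(m < 0):
            raise ConfigurationError("transition probabilities must be >= 0")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError("transition-matrix rows must sum to 1")
        self.stage_transition_matrix = m
        n_ep = self.night_duration / self.epoch_length
        if abs(n_ep - round(n_ep)) > 1e-9:
            raise ConfigurationError(
                "night_duration must be an integer multiple of epoch_length"
            )
        for name in ("spindle_density_target", "so_density_target", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def n_epochs(self) -> int:
        return int(round(self.night_duration / self.epoch_length))


@dataclass
class GroundTruth:
    """Injected events of one synthesized night.

    Event tuples are ``(onset_s, offset_s, amplitude_uV)`` for spindles
    and ``(onset_s, offset_s, polarity, amplitude_uV)`` for half-waves;
    times are seconds from lights out.  ``delta_power`` is the injected
    background delta-band (0.75-4.5 Hz) power per epoch in uV^2.
    """

    spindle_events: List[Tuple[float, float, float]]
    so_events: List[Tuple[float, float, str, float]]
    delta_power: np.ndarray

    def to_dict(self) -> dict:
        return {
            "spindle_events": [list(e) for e in self.spindle_events],
            "so_events": [list(e) for e in self.so_events],
            "delta_power": list(map(float, self.delta_power)),
        }


def _stim_active(condition: str, epoch: int, n2_run: int, stim_window: int) -> bool:
    if condition == "C2":
        return epoch < stim_window
    if condition == "C1":
        return n2_run < 3 and epoch < stim_window
    return False


def _shift_row(row: np.ndarray, shift: float) -> np.ndarray:
    """Add ``shift`` to the N2 column and renormalize the rest."""
    row = row.copy()
    n2 = STAGES.index("N2")
    target = min(max(row[n2] + shift, 0.0), 0.995)
    rest = 1.0 - row[n2]
    if rest <= 0:
        return row
    row *= (1.0 - target) / rest
    row[n2] = target
    return row


def generate_hypnogram(
    config: SimulationConfig,
    subject_id: int = 0,
    condition: str = "B",
) -> EpochedHypnogram:
    """Simulate one night's stage sequence and artifact flags.

    The chain starts in W at lights out.  Under C1/C2 the N2 dwell shift
    of ``config.condition_effects`` applies while stimulation is on.
    Nights lacking a run of three consecutive N2 epochs are re-drawn from
    the next sub-stream (they are vanishingly rare at full night length).
    """
    n_ep = config.n_epochs
    P = config.stage_transition_matrix
    shift = config.condition_effects.n2_dwell_shift if condition in ("C1", "C2") else 0.0
    for attempt in range(200):
        rng = stream_rng(config.seed, "hypnogram", subject_id, condition, attempt)
        stages = np.empty(n_ep, dtype=object)
        stages[0] = "W"
        state = 0
        n2_run = 0
        for i in range(1, n_ep):
            row = P[state]
            if shift and _stim_active(condition, i, n2_run, config.stim_window_epochs):
                row = _shift_row(row, shift)
            state = rng.choice(5, p=row)
            stages[i] = STAGES[state]
            n2_run = n2_run + 1 if STAGES[state] == "N2" else 0
        has_run = _has_n2_run(stages)
        if has_run or n_ep < 4:
            break
    else:
        warnings.warn("no 3-epoch N2 run after 200 attempts; returning last draw")
    art_rng = stream_rng(config.seed, "artifact", subject_id, condition)
    flags = art_rng.random(n_ep) < config.artifact_rate
    return EpochedHypnogram(
        stages=stages,
        artifact_flags=flags,
        lights_out_epoch=0,
        epoch_length=config.epoch_length,
    )


def _has_n2_run(stages: Sequence[str], length: int = 3) -> bool:
    run = 0
    for s in stages:
        run = run + 1 if s == "N2" else 0
        if run >= length:
            return True
    return False


def _shaped_background(
    rng: np.random.Generator, n: int, fs: float, exponent: float, rms: float
) -> Tuple[np.ndarray, float]:
    """1/f^exponent Gaussian noise; returns (signal, delta-band power uV^2)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.zeros(freqs.size, dtype=complex)
    nz = freqs > 0
    phases = rng.standard_normal(nz.sum()) + 1j * rng.standard_normal(nz.sum())
    spec[nz] = phases * freqs[nz] ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n)
    std = x.std()
    if std > 0:
        scale = rms / std
        x *= scale
        spec *= scale
    # Parseval: per-bin variance contribution of a one-sided rfft spectrum.
    band = (freqs >= 0.75) & (freqs <= 4.5)
    delta = float(2.0 * np.sum(np.abs(spec[band]) ** 2) / n**2)
    return x, delta


def _place_events(
    rng: np.random.Generator,
    durations: Sequence[float],
    epoch_length: float,
    min_gap: float,
) -> List[Tuple[int, float]]:
    """Non-overlapping random offsets within one epoch (greedy with retry).

    Returns ``(duration_index, offset)`` pairs; events that cannot be
    placed in a crowded epoch are silently dropped.
    """
    placed: List[Tuple[float, float]] = []
    out: List[Tuple[int, float]] = []
    for k, dur in enumerate(durations):
        ok = None
        for _ in range(40):
            start = rng.uniform(0.0, max(epoch_length - dur, 1e-6))
            if all(
                start >= e + min_gap or start + dur + min_gap <= s
                for s, e in placed
            ):
                ok = start
                break
        if ok is None:
            continue  # epoch too crowded; drop the event
        placed.append((ok, ok + dur))
        out.append((k, ok))
    return out


def _count_from_density(rng: np.random.Generator, density: float) -> int:
    base = int(math.floor(density))
    return base + (1 if rng.random() < density - base else 0)


def synthesize_eeg(
    hypnogram: EpochedHypnogram,
    config: SimulationConfig,
    seed: Optional[int] = None,
    subject_id: int = 0,
    condition: str = "B",
) -> Tuple[EEGRecording, GroundTruth]:
    """Synthesize Cz-referenced F3/C3/A2 channels plus ground truth.

    Spindles are injected on C3 (attenuated on F3), slow-oscillation
    cycles on F3 (attenuated on C3), waking alpha on both; A2 carries
    small independent mastoid noise, so the C3-A2 / F3-A2 derivations
    recover the injected signals.
    """
    if config.sampling_rate < 30:
        raise ConfigurationError(
            "sampling_rate must be >= 30 Hz (sigma band unrepresentable)"
        )
    fs = config.sampling_rate
    seed = config.seed if seed is None else seed
    ep_len = hypnogram.epoch_length
    spe = int(round(ep_len * fs))
    n_ep = hypnogram.n_epochs
    n = n_ep * spe

    bg_rng = stream_rng(seed, "background", subject_id, condition)
    ev_rng = stream_rng(seed, "events", subject_id, condition)
    mast_rng = stream_rng(seed, "mastoid", subject_id, condition)

    c3 = np.empty(n)
    f3 = np.empty(n)
    delta_power = np.empty(n_ep)
    spindle_truth: List[Tuple[float, float, float]] = []
    so_truth: List[Tuple[float, float, str, float]] = []

    stages = hypnogram.stages
    eff = config.condition_effects
    n2_run = 0
    for i in range(n_ep):
        stage = stages[i]
        beta = (
            config.background_exponent_nrem
            if stage in NREM
            else config.background_exponent_wake
        )
        rms = config.stage_rms.get(stage, 10.0)
        bg_c3, delta = _shaped_background(bg_rng, spe, fs, beta, rms)
        bg_f3, _ = _shaped_background(bg_rng, spe, fs, beta, rms)
        delta_power[i] = delta
        sl = slice(i * spe, (i + 1) * spe)
        c3[sl] = bg_c3
        f3[sl] = bg_f3
        t0 = i * ep_len

        if stage == "W":
            phase = ev_rng.uniform(0, 2 * np.pi)
            tt = np.arange(spe) / fs
            alpha = config.wake_alpha_amp * np.sin(2 * np.pi * 10.0 * tt + phase)
            c3[sl] += alpha
            f3[sl] += alpha
            n2_run = 0
            continue
        n2_run = n2_run + 1 if stage == "N2" else 0
        if stage not in NREM:
            continue

        sp_density = config.spindle_density_target
        if condition in ("C1", "C2") and _stim_active(
            condition, i, n2_run, config.stim_window_epochs
        ):
            sp_density = max(sp_density + eff.spindle_density_shift, 0.0)
        n_spindles = _count_from_density(ev_rng, sp_density)
        n_so_pairs = _count_from_density(ev_rng, config.so_density_target / 2.0)

        # slow oscillations first (longer events, harder to place)
        so_durs = 1.0 / ev_rng.uniform(*config.so_freq_range, size=n_so_pairs)
        sp_durs = ev_rng.uniform(*config.spindle_duration_range, size=n_spindles)
        placements = _place_events(
            ev_rng,
            list(so_durs) + list(sp_durs),
            ep_len,
            config.min_event_gap,
        )
        for k, off in placements:
            if k < n_so_pairs:
                dur = so_durs[k]
                amp = ev_rng.uniform(*config.so_amp_range)
                sign = 1.0 if ev_rng.random() < 0.5 else -1.0
                m = int(round(dur * fs))
                tt = np.arange(m) / fs
                wave = sign * amp * np.sin(2 * np.pi * tt / dur)
                a = i * spe + int(round(off * fs))
                b = min(a + m, n)
                f3[a:b] += wave[: b - a]
                c3[a:b] += 0.5 * wave[: b - a]
                half = dur / 2.0
                pol1 = "positive" if sign > 0 else "negative"
                pol2 = "negative" if sign > 0 else "positive"
                so_truth.append((t0 + off, t0 + off + half, pol1, amp))
                so_truth.append((t0 + off + half, t0 + off + dur, pol2, amp))
            else:
                dur = sp_durs[k - n_so_pairs]
                amp = ev_rng.uniform(*config.spindle_amp_range)
                freq = ev_rng.uniform(*config.spindle_freq_range)
                phase = ev_rng.uniform(0, 2 * np.pi)
                m = int(round(dur * fs))
                tt = np.arange(m) / fs
                env = np.hanning(m)
                burst = amp * env * np.sin(2 * np.pi * freq * tt + phase)
                a = i * spe + int(round(off * fs))
                b = min(a + m, n)
                c3[a:b] += burst[: b - a]
                f3[a:b] += 0.3 * burst[: b - a]
                spindle_truth.append((t0 + off, t0 + off + dur, amp))

    a2 = 2.0 * mast_rng.standard_normal(n)
    rec = EEGRecording(
        samples=np.vstack([f3, c3, a2]),
        sampling_rate=fs,
        channel_labels=["F3", "C3", "A2"],
        reference="Cz",
    )
    truth = GroundTruth(
        spindle_events=sorted(spindle_truth),
        so_events=sorted(so_truth),
        delta_power=delta_power,
    )
    return rec, truth


def generate_wordpair_data(
    config: SimulationConfig,
    architecture_features: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
    immediate_mean: float = 26.0,
    immediate_sd: float = 5.0,
    improvement_mean: float = 6.7,
    improvement_sd: float = 3.7,
    feature_correlation: float = 0.0,
    ceiling_fraction: float = 0.0,
) -> pd.DataFrame:
    """Simulate immediate/delayed word-pair scores per subject x condition.

    ``architecture_features``, if given, is a tidy frame with columns
    (subject, condition, value) -- e.g. spindle counts -- and immediate
    recall is drawn with Pearson correlation ``feature_correlation`` to
    that feature via a Gaussian copula.  Scores land on the 0-40
    half-point grid; overnight improvement is added on top of immediate
    recall.  A ``ceiling_fraction`` of subjects is forced to the 40-point
    ceiling (delayed recall of one night); everyone else is capped at
    39.5 so the forced count is exact.
    """
    seed = config.seed if seed is None else seed
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    feat = None
    if architecture_features is not None and feature_correlation != 0.0:
        feat = architecture_features.set_index(["subject", "condition"])["value"]
        mu, sd = feat.mean(), feat.std(ddof=0)
        sd = sd if sd > 0 else 1.0

    n_ceiling = int(round(ceiling_fraction * config.n_subjects))
    ceil_rng = stream_rng(seed, "wordpair-ceiling")
    ceiling_subjects = set(
        ceil_rng.choice(subjects, size=n_ceiling, replace=False)
    ) if n_ceiling else set()

    rows = []
    for subj in subjects:
        ceil_cond = None
        if subj in ceiling_subjects:
            ceil_cond = stream_rng(seed, "wordpair-ceilnight", subj).choice(
                list(config.conditions)
            )
        for cond in config.conditions:
            rng = stream_rng(seed, "wordpair", subj, cond)
            eps = rng.standard_normal()
            if feat is not None and (subj, cond) in feat.index:
                z_feat = (feat.loc[(subj, cond)] - mu) / sd
                z = (
                    feature_correlation * z_feat
                    + math.sqrt(1 - feature_correlation**2) * eps
                )
            else:
                z = eps
            immediate = immediate_mean + immediate_sd * z
            improvement = rng.normal(improvement_mean, improvement_sd)
            delayed = immediate + improvement
            cap = 40.0 if cond == ceil_cond else 39.5
            immediate = min(max(round(immediate * 2) / 2, 0.0), cap)
            delayed = min(max(round(delayed * 2) / 2, 0.0), cap)
            if cond == ceil_cond:
                delayed = 40.0
            rows.append(
                {
                    "subject": subj,
                    "condition": cond,
                    "immediate": immediate,
                    "delayed": delayed,
                }
            )
    return pd.DataFrame(rows)


def match_events(
    detected: Sequence[Tuple[float, float]],
    truth: Sequence[Tuple[float, float]],
    tolerance: float = 0.25,
) -> Tuple[float, float]:
    """Sensitivity and precision of detected intervals against ground truth.

    Greedy one-to-one matching: a detected event matches a truth event
    when their intervals overlap, or their onsets differ by at most
    ``tolerance`` seconds.  Returns ``(sensitivity, precision)``.
    """
    truth = sorted(truth)
    detected = sorted(detected)
    used = [False] * len(truth)
    tp = 0
    for d0, d1 in detected:
        for j, (t0, t1) in enumerate(truth):
            if used[j]:
                continue
            overlap = min(d1, t1) - max(d0, t0)
            if overlap > 0 or abs(d0 - t0) <= tolerance:
                used[j] = True
                tp += 1
                break
    sens = tp / len(truth) if truth else math.nan
    prec = tp / len(detected) if detected else math.nan
    return sens, prec
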