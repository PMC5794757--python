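"""Band-power spectral analysis of sleep EEG.

Each 20-s scoring epoch is decomposed into five non-overlapping 4-s
segments; a Hann-windowed periodogram (0.25-Hz resolution) is computed per
segment and averaged.  The density normalization is chosen so that the
band-integrated power of a pure sinusoid equals amplitude^2/2 (its
mean-square value), making band powers directly interpretable in uV^2.

Band definitions follow the study: delta 0.75-4.5 Hz, theta 4.5-9 Hz,
alpha 9-15 Hz, sigma 11-15 Hz, beta 15-25 Hz.  Band edges are *inclusive*
on both sides, so a bin sitting exactly on a shared edge (4.5 Hz) is
counted in both neighbouring bands, and alpha deliberately overlaps sigma
entirely -- both are computed independently, as tabulated in the study.
Delta can additionally be split into <1 Hz, 1-2 Hz and 2-4 Hz sub-bands.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import AnalysisWindow, EEGRecording, EpochedHypnogram

__all__ = [
    "BANDS",
    "SUB_DELTA_BANDS",
    "NREM_STAGES",
    "rereference",
    "epoch_spectra",
    "band_power",
    "nrem_band_means",
    "delta_buildup",
]

#: Study band definitions in Hz (inclusive edges).
BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (0.75, 4.5),
    "theta": (4.5, 9.0),
    "alpha": (9.0, 15.0),
    "sigma": (11.0, 15.0),
    "beta": (15.0, 25.0),
}

#: Sub-division of the delta range: <1 Hz, 1-2 Hz, 2-4 Hz oscillations.
SUB_DELTA_BANDS: Dict[str, Tuple[float, float]] = {
    "delta_sub1": (0.75, 1.0),
    "delta_1_2": (1.0, 2.0),
    "delta_2_4": (2.0, 4.0),
}

#: Stages counted as NREM for spectra and event densities.
NREM_STAGES = frozenset({"N1", "N2", "N3"})

SEGMENT_S = 4.0
SEGMENTS_PER_EPOCH = 5


def rereference(rec: EEGRecording, target: str) -> EEGRecording:
    """Re-reference to a mastoid derivation such as ``"C3-A2"``.

    Inputs are common-referenced (e.g. to Cz); the derivation is the
    sample-wise difference of the two named channels, which cancels the
    common reference: (C3-Cz) - (A2-Cz) = C3-A2.
    """
    try:
        active, ref = target.split("-")
    except ValueError:
        raise ValueError(f"derivation must look like 'C3-A2', got {target!r}")
    data = rec.channel(active) - rec.channel(ref)
    return EEGRecording(
        samples=data[np.newaxis, :],
        sampling_rate=rec.sampling_rate,
        channel_labels=[target],
        reference=ref,
    )


def epoch_spectra(
    rec: EEGRecording,
    hypnogram: EpochedHypnogram,
    channel: Optional[str] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-epoch power density spectra (uV^2/Hz) of one derivation.

    Returns ``(freqs, psd)`` with ``psd`` of shape (n_epochs, n_freqs) and
    0.25-Hz resolution.  The recording must start at lights out and cover
    every hypnogram epoch after lights out.
    """
    x = rec.channel(channel) if channel else rec.samples[0]
    fs = rec.sampling_rate
    nper = int(round(SEGMENT_S * fs))
    epoch_samples = nper * SEGMENTS_PER_EPOCH
    n_epochs = hypnogram.n_epochs_after_lights_out
    if x.size < n_epochs * epoch_samples:
        raise ValueError(
            f"recording ({x.size} samples) shorter than hypnogram "
            f"({n_epochs} epochs x {epoch_samples} samples)"
        )
    blocks = x[: n_epochs * epoch_samples].reshape(n_epochs, epoch_samples)
    # Welch with non-overlapping 4-s Hann segments == mean of 5 periodograms.
    freqs, psd = sps.welch(
        blocks,
        fs=fs,
        window="hann",
        nperseg=nper,
        noverlap=0,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def _band_bins(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    if high < low:
        raise ValueError(f"empty band: ({low}, {high})")
    if high > freqs[-1] + 1e-12:
        raise ValueError(f"band ({low}, {high}) exceeds Nyquist {freqs[-1]}")
    df = freqs[1] - freqs[0]
    if high - low < df - 1e-12:
        raise ValueError(f"band ({low}, {high}) narrower than resolution {df}")
    return (freqs >= low - 1e-12) & (freqs <= high + 1e-12)


def band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> pd.DataFrame:
    """Integrate per-epoch spectra over bands; returns epochs x bands, uV^2.

    Edges are inclusive on both sides; overlapping bands are integrated
    independently.
    """
    if bands is None:
        bands = BANDS
    df = freqs[1] - freqs[0]
    psd = np.atleast_2d(psd)
    out = {}
    for name, (lo, hi) in bands.items():
        mask = _band_bins(freqs, lo, hi)
        out[name] = psd[:, mask].sum(axis=1) * df
    return pd.DataFrame(out)


def nrem_band_means(
    series: pd.DataFrame,
    hypnogram: EpochedHypnogram,
    window: AnalysisWindow,
    stages: Iterable[str] = NREM_STAGES,
) -> pd.Series:
    """Mean band power over artifact-free NREM epochs within the window.

    Returns one scalar per band; all-nan when no eligible epoch exists.
    """
    window = window.clip_to(hypnogram)
    stage_arr = hypnogram.stage_array()
    art = hypnogram.artifact_array()
    stages = set(stages)
    eligible = np.array(
        [
            (s in stages) and not a
            for s, a in zip(stage_arr, art)
        ]
    )
    eligible[: window.start_epoch] = False
    eligible[window.end_epoch :] = False
    idx = np.nonzero(eligible)[0]
    if idx.size == 0:
        return pd.Series(math.nan, index=series.columns)
    return series.iloc[idx].mean()


def delta_buildup(
    series: pd.DataFrame,
    hypnogram: EpochedHypnogram,
    band: str = "delta",
    n_epochs: int = 180,
    smooth: int = 7,
) -> np.ndarray:
    """Smoothed delta-power time course over the first hour after sleep onset.

    Takes the ``band`` power of the ``n_epochs`` (default 180 = 1 h) epochs
    following sleep onset and applies a centered moving average over
    ``smooth`` epochs, with shrinking windows at the edges.  Raises when
    sleep onset is absent or the night is too short.
    """
    onset = hypnogram.sleep_onset_epoch()
    if onset is None:
        raise ValueError("no sleep onset (no N2 epoch) in hypnogram")
    if len(series) - onset < n_epochs:
        raise ValueError(
            f"need {n_epochs} epochs after sleep onset, have {len(series) - onset}"
        )
    x = series[band].to_numpy()[onset : onset + n_epochs]
    return (
        pd.Series(x)
        .rolling(smooth, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
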