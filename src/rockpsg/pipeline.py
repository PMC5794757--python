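"""End-to-end pipeline: simulate -> detect -> tabulate -> compare.

``run_pipeline`` produces, for every subject x condition night, the
architecture report, NREM band powers, spindle and slow-oscillation
events and densities over each configured analysis window, plus word-pair
scores, and runs the condition statistics on the pooled cohort tables.
Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import architecture as arch
from . import slow_waves as sw
from . import spectral
from . import spindles as sp
from .core import AnalysisWindow, EpochedHypnogram, FIRST_2H, FIRST_3H
from .stats import CohortTable, condition_anova, pearson_with_bonferroni, wordpair_model
from .synthetic import SimulationConfig, generate_hypnogram, generate_wordpair_data, synthesize_eeg
from .wordpair import WordPairSession, apply_ceiling_exclusion, sessions_to_frame

log = logging.getLogger("rockpsg")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full simulated-cohort analysis run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    windows: Optional[Dict[str, AnalysisWindow]] = None  # None -> night/2h/3h
    bands: Dict[str, tuple] = field(default_factory=lambda: dict(spectral.BANDS))
    spindle_duration_bounds: tuple = sp.DURATION_BOUNDS_S
    so_restrict_to_nrem: bool = True
    wordpair_feature_correlation: float = 0.6
    wordpair_ceiling_fraction: float = 2.0 / 18.0
    out_dir: Optional[Path] = None

    def resolve_windows(self, h: EpochedHypnogram) -> Dict[str, AnalysisWindow]:
        if self.windows is not None:
            return {k: w.clip_to(h) for k, w in self.windows.items()}
        wins = {"entire_night": AnalysisWindow.entire(h)}
        for name, win in (("first_2h", FIRST_2H), ("first_3h", FIRST_3H)):
            if win.start_epoch < h.n_epochs_after_lights_out:
                wins[name] = win.clip_to(h)
        return wins


def _night_features(cfg: PipelineConfig, subject: str, condition: str):
    sim = cfg.simulation
    subj_idx = int(subject.lstrip("S")) - 1
    h = generate_hypnogram(sim, subj_idx, condition)
    rec, truth = synthesize_eeg(h, sim, subject_id=subj_idx, condition=condition)
    c3a2 = spectral.rereference(rec, "C3-A2")
    f3a2 = spectral.rereference(rec, "F3-A2")
    fs = rec.sampling_rate

    freqs, psd = spectral.epoch_spectra(c3a2, h)
    bp = spectral.band_power(freqs, psd, cfg.bands)

    filtered = sp.sigma_filter(c3a2.samples[0], fs)
    thr = sp.estimate_thresholds(filtered, h, fs)
    sp_events = sp.detect_spindles(
        filtered, thr, h, fs, duration_bounds=cfg.spindle_duration_bounds
    )
    log.info(
        "%s/%s: spindle thresholds lower=%.3f upper=%.3f uV, %d events",
        subject, condition, thr.lower, thr.upper, len(sp_events),
    )
    sw_signal = sw.sw_preprocess(f3a2.samples[0], fs)
    sw_events = sw.detect_half_waves(sw_signal)

    records = []
    for wname, win in cfg.resolve_windows(h).items():
        rep = arch.architecture_report(h, win)
        for metric, value in rep.to_series().items():
            records.append((f"{metric}:{wname}", value))
        means = spectral.nrem_band_means(bp, h, win)
        for band, value in means.items():
            records.append((f"{band}_power:{wname}", value))
        n_spindle, d_spindle = sp.spindle_counts(sp_events, h, win)
        records.append((f"spindle_count:{wname}", n_spindle))
        records.append((f"spindle_density:{wname}", d_spindle))
        n_so, d_so = sw.so_counts(
            sw_events, h, win, restrict_to_nrem=cfg.so_restrict_to_nrem
        )
        records.append((f"so_count:{wname}", n_so))
        records.append((f"so_density:{wname}", d_so))
    return h, sp_events, sw_events, records


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Run the full simulated study; returns the report bundle.

    Keys: ``features`` (tidy CohortTable frame), ``anova`` (per-feature
    ComparisonResult), ``wordpair`` (sessions frame), ``wordpair_models``,
    ``correlations``, ``spindle_events``/``so_events`` frames.
    """
    sim = cfg.simulation
    subjects = [f"S{i + 1:02d}" for i in range(sim.n_subjects)]
    feat_rows, spindle_rows, so_rows = [], [], []
    for subject in subjects:
        for condition in sim.conditions:
            try:
                h, spe, swe, records = _night_features(cfg, subject, condition)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"pipeline failed at stage 'night' for {subject}/{condition}: {exc}"
                ) from exc
            for feature, value in records:
                feat_rows.append(
                    {"subject": subject, "condition": condition,
                     "feature": feature, "value": value}
                )
            for e in spe:
                spindle_rows.append(
                    {"subject": subject, "condition": condition, "onset_s": e.onset,
                     "offset_s": e.offset, "duration_s": e.duration,
                     "peak_uV": e.peak_amplitude, "epoch_index": e.epoch_index}
                )
            for e in swe:
                so_rows.append(
                    {"subject": subject, "condition": condition,
                     "polarity": e.polarity, "start_s": e.start, "end_s": e.end,
                     "peak_uV": e.peak_amplitude, "epoch_index": e.epoch_index}
                )

    features = pd.DataFrame(feat_rows)
    table = CohortTable(features)

    anova = {}
    for feature in table.features():
        vals = features.loc[features["feature"] == feature, "value"]
        if vals.isna().any() or not np.isfinite(vals).all():
            continue
        anova[feature] = condition_anova(table, feature)

    # word-pair task correlated with the full-night spindle count
    spindle_feature = features[features["feature"] == "spindle_count:entire_night"]
    wp = generate_wordpair_data(
        sim,
        architecture_features=spindle_feature[["subject", "condition", "value"]],
        feature_correlation=cfg.wordpair_feature_correlation,
        ceiling_fraction=cfg.wordpair_ceiling_fraction,
    )
    sessions = apply_ceiling_exclusion(
        [
            WordPairSession.from_points(
                r.subject, r.condition, r.immediate, r.delayed
            )
            for r in wp.itertuples()
        ]
    )
    wp_models = {
        feature: wordpair_model(sessions, feature)
        for feature in ("improvement", "immediate", "delayed", "acquisition")
    }

    correlations = _spindle_recall_correlations(features, sessions)

    bundle: Dict[str, object] = {
        "features": features,
        "anova": anova,
        "wordpair": sessions_to_frame(sessions),
        "wordpair_models": wp_models,
        "correlations": correlations,
        "spindle_events": pd.DataFrame(spindle_rows),
        "so_events": pd.DataFrame(so_rows),
    }
    if cfg.out_dir is not None:
        _write_bundle(bundle, Path(cfg.out_dir))
    return bundle


def _spindle_recall_correlations(features: pd.DataFrame, sessions) -> pd.DataFrame:
    """Per-condition Pearson correlations of spindle features vs recall.

    Four recall measures per spindle feature -> Bonferroni alpha 0.0125.
    """
    from .wordpair import initial_acquisition_rate, overnight_improvement

    kept = [s for s in sessions if not s.excluded]
    measures = {
        "improvement": {(s.subject, s.condition): overnight_improvement(s) for s in kept},
        "immediate": {(s.subject, s.condition): s.immediate_score for s in kept},
        "delayed": {(s.subject, s.condition): s.delayed_score for s in kept},
        "acquisition": {(s.subject, s.condition): initial_acquisition_rate(s) for s in kept},
    }
    rows = []
    for feature in ("spindle_count:entire_night", "spindle_density:entire_night",
                    "sigma_power:entire_night"):
        sub = features[features["feature"] == feature]
        if sub.empty:
            continue
        for condition, grp in sub.groupby("condition"):
            vals = {(r.subject, r.condition): r.value for r in grp.itertuples()}
            for mname, mvals in measures.items():
                keys = sorted(set(vals) & set(mvals))
                if len(keys) < 3:
                    continue
                x = [vals[k] for k in keys]
                y = [mvals[k] for k in keys]
                r, p, sig = pearson_with_bonferroni(x, y, n_tests=4)
                rows.append(
                    {"feature": feature, "condition": condition, "measure": mname,
                     "r": r, "p": p, "significant": sig, "n": len(keys)}
                )
    return pd.DataFrame(rows)


def _write_bundle(bundle: Dict[str, object], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["features"].to_csv(out_dir / "features.csv", index=False)
    bundle["wordpair"].to_csv(out_dir / "wordpair_sessions.csv", index=False)
    bundle["spindle_events"].to_csv(out_dir / "spindle_events.csv", index=False)
    bundle["so_events"].to_csv(out_dir / "so_events.csv", index=False)
    bundle["correlations"].to_csv(out_dir / "correlations.csv", index=False)
    rows = []
    for feature, res in bundle["anova"].items():
        for pw in res.pairwise.itertuples():
            rows.append(
                {"feature": feature, "F": res.f_statistic, "p_omnibus": res.p_value,
                 "pair": f"{pw.condition_1}-{pw.condition_2}",
                 "mean_diff": pw.mean_diff, "p_pairwise": pw.p,
                 "d_corrected": pw.d_corrected}
            )
    pd.DataFrame(rows).to_csv(out_dir / "comparisons.csv", index=False)
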