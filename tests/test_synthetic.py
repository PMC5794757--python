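"""Synthetic cohort generator: calibration, ground truth, determinism."""

import numpy as np
import pandas as pd
import pytest

from rockpsg.architecture import sleep_efficiency
from rockpsg.core import AnalysisWindow, ConfigurationError, EpochedHypnogram, STAGES
from rockpsg.synthetic import (
    DEFAULT_TRANSITION_MATRIX,
    SimulationConfig,
    generate_hypnogram,
    generate_wordpair_data,
    synthesize_eeg,
)


def forced_chain_matrix():
    """W -> N1 -> N2 -> N2 -> ... deterministic chain."""
    P = np.zeros((5, 5))
    P[0, 1] = 1.0  # W -> N1
    P[1, 2] = 1.0  # N1 -> N2
    P[2, 2] = 1.0  # N2 absorbing
    P[3, 3] = 1.0
    P[4, 4] = 1.0
    return P


# ---------------------------------------------------------------- hypnogram

def test_forced_chain_first_n2_at_epoch_2():
    cfg = SimulationConfig(
        night_duration=200.0, stage_transition_matrix=forced_chain_matrix()
    )
    h = generate_hypnogram(cfg, 0, "B")
    assert h.stages[0] == "W"
    assert h.sleep_onset_epoch() == 2
    assert all(s == "N2" for s in h.stages[2:])


def test_invalid_transition_matrix_rejected():
    bad = DEFAULT_TRANSITION_MATRIX.copy()
    bad[0, 0] += 0.01
    with pytest.raises(ConfigurationError):
        SimulationConfig(stage_transition_matrix=bad)
    with pytest.raises(ConfigurationError):
        SimulationConfig(night_duration=28810.0)  # not a multiple of 20 s
    with pytest.raises(ConfigurationError):
        SimulationConfig(spindle_density_target=-1.0)


def test_zero_artifact_rate_means_no_flags():
    cfg = SimulationConfig(night_duration=2000.0, artifact_rate=0.0)
    h = generate_hypnogram(cfg, 0, "B")
    assert not h.artifact_flags.any()


def test_baseline_sleep_efficiency_matches_study_scale():
    """Mean efficiency of 100 simulated baseline nights within +-3 points
    of the published 96.77%."""
    cfg = SimulationConfig(seed=5)
    effs = [
        sleep_efficiency(h, AnalysisWindow.entire(h))
        for h in (generate_hypnogram(cfg, s, "B") for s in range(100))
    ]
    assert abs(np.mean(effs) - 96.77) <= 3.0


def test_stage_fractions_approach_stationary_distribution():
    """At 10x night length the empirical stage fractions sit near the
    chain's stationary distribution (averaged over a few nights)."""
    w, v = np.linalg.eig(DEFAULT_TRANSITION_MATRIX.T)
    st = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    st /= st.sum()
    cfg = SimulationConfig(night_duration=288000.0, seed=1)
    fracs = np.zeros(5)
    n_nights = 5
    for s in range(n_nights):
        h = generate_hypnogram(cfg, s, "B")
        fracs += np.array([(h.stages == lbl).mean() for lbl in STAGES])
    fracs /= n_nights
    assert np.abs(fracs - st).max() <= 0.02


def test_c2_condition_shifts_n2_in_stim_window_only():
    cfg = SimulationConfig(seed=11)
    n2_base, n2_stim = [], []
    for s in range(30):
        hb = generate_hypnogram(cfg, s, "B")
        hc = generate_hypnogram(cfg, s, "C2")
        n2_base.append((hb.stages[:360] == "N2").mean())
        n2_stim.append((hc.stages[:360] == "N2").mean())
    assert np.mean(n2_stim) > np.mean(n2_base)


def test_identical_seeds_bit_identical():
    cfg = SimulationConfig(night_duration=1200.0, sampling_rate=128.0, seed=9)
    h1 = generate_hypnogram(cfg, 1, "C1")
    h2 = generate_hypnogram(cfg, 1, "C1")
    assert (h1.stages == h2.stages).all()
    assert (h1.artifact_flags == h2.artifact_flags).all()
    r1, t1 = synthesize_eeg(h1, cfg, subject_id=1, condition="C1")
    r2, t2 = synthesize_eeg(h2, cfg, subject_id=1, condition="C1")
    assert np.array_equal(r1.samples, r2.samples)
    assert t1.spindle_events == t2.spindle_events


def test_adding_subjects_does_not_perturb_existing_nights():
    cfg = SimulationConfig(night_duration=1200.0, sampling_rate=128.0, seed=4)
    h_alone = generate_hypnogram(cfg, 0, "B")
    # generating other subjects first must not change subject 0
    for s in (5, 3, 7):
        generate_hypnogram(cfg, s, "B")
    h_again = generate_hypnogram(cfg, 0, "B")
    assert (h_alone.stages == h_again.stages).all()


# ---------------------------------------------------------------------- EEG

def test_zero_densities_give_empty_ground_truth():
    cfg = SimulationConfig(
        night_duration=400.0, sampling_rate=128.0,
        spindle_density_target=0.0, so_density_target=0.0, wake_alpha_amp=0.0,
    )
    h = generate_hypnogram(cfg, 0, "B")
    _, truth = synthesize_eeg(h, cfg)
    assert truth.spindle_events == []
    assert truth.so_events == []


def test_low_sampling_rate_rejected():
    cfg = SimulationConfig(night_duration=400.0, sampling_rate=256.0)
    h = generate_hypnogram(cfg, 0, "B")
    cfg.sampling_rate = 25.0
    with pytest.raises(ConfigurationError):
        synthesize_eeg(h, cfg)


def test_ground_truth_events_within_recording_and_sigma_band():
    cfg = SimulationConfig(night_duration=1200.0, sampling_rate=128.0, seed=2)
    h = generate_hypnogram(cfg, 0, "B")
    rec, truth = synthesize_eeg(h, cfg)
    for onset, offset, amp in truth.spindle_events:
        assert 0 <= onset < offset <= rec.duration_s
        assert amp > 0
    for onset, offset, pol, amp in truth.so_events:
        assert 0 <= onset < offset <= rec.duration_s
        assert pol in ("positive", "negative")
    assert truth.delta_power.shape == (h.n_epochs,)
    assert (truth.delta_power >= 0).all()


def test_n3_background_has_more_delta_than_n1():
    from rockpsg import spectral

    cfg = SimulationConfig(
        night_duration=1200.0, sampling_rate=128.0, seed=6,
        spindle_density_target=0.0, so_density_target=0.0,
    )
    means = {}
    for stage in ("N1", "N3"):
        h = EpochedHypnogram(stages=[stage] * 60)
        rec, _ = synthesize_eeg(h, cfg)
        deriv = spectral.rereference(rec, "C3-A2")
        freqs, psd = spectral.epoch_spectra(deriv, h)
        bp = spectral.band_power(freqs, psd)
        means[stage] = bp["delta"].mean()
    assert means["N3"] > means["N1"]


# ---------------------------------------------------------------- word-pair

def test_wordpair_no_improvement_no_noise_delayed_equals_immediate():
    cfg = SimulationConfig(n_subjects=10)
    df = generate_wordpair_data(
        cfg, improvement_mean=0.0, improvement_sd=0.0
    )
    assert (df["delayed"] == df["immediate"]).all()


def test_wordpair_forced_ceiling_fraction():
    cfg = SimulationConfig(n_subjects=18)
    df = generate_wordpair_data(cfg, ceiling_fraction=2.0 / 18.0)
    at_ceiling = df[(df["immediate"] >= 40) | (df["delayed"] >= 40)]
    assert at_ceiling["subject"].nunique() == 2


def test_wordpair_scores_on_half_point_grid():
    cfg = SimulationConfig(n_subjects=12)
    df = generate_wordpair_data(cfg)
    for col in ("immediate", "delayed"):
        assert np.allclose(df[col] * 2, np.round(df[col] * 2))
        assert df[col].between(0, 40).all()


def test_wordpair_correlation_recovers_generative_parameter():
    """Monte-Carlo: the sample spindle-recall correlation concentrates
    near the requested copula parameter (0.7 at n=16, 200 replicates)."""
    cfg = SimulationConfig(n_subjects=16, conditions=("B",))
    rng = np.random.default_rng(0)
    rs = []
    for rep in range(200):
        feat = pd.DataFrame(
            {
                "subject": [f"S{i + 1:02d}" for i in range(16)],
                "condition": "B",
                "value": rng.normal(600, 180, size=16),
            }
        )
        df = generate_wordpair_data(
            cfg, architecture_features=feat, seed=rep, feature_correlation=0.7
        )
        r = np.corrcoef(
            feat["value"],
            df.set_index("subject").loc[feat["subject"], "immediate"],
        )[0, 1]
        rs.append(r)
    assert abs(np.mean(rs) - 0.7) <= 0.1
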