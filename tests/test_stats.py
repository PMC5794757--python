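"""Block ANOVA, LSD post hocs, effect sizes, and correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from rockpsg.stats import (
    CohortTable,
    cohens_d,
    condition_anova,
    pearson_with_bonferroni,
    wordpair_model,
)
from rockpsg.wordpair import WordPairSession


def make_table(values: np.ndarray, conditions=("B", "C1", "C2"), feature="x"):
    """values: subjects x conditions matrix."""
    rows = []
    for i, row in enumerate(values):
        for j, cond in enumerate(conditions):
            rows.append(
                {"subject": f"S{i:02d}", "condition": cond,
                 "feature": feature, "value": row[j]}
            )
    return CohortTable(pd.DataFrame(rows))


# ------------------------------------------------------------------- anova

def test_identical_values_give_f_zero_p_one():
    table = make_table(np.full((6, 3), 4.2))
    res = condition_anova(table, "x")
    assert res.f_statistic == 0.0
    assert res.p_value == 1.0
    assert (res.pairwise["p"] == 1.0).all()


def test_two_conditions_f_equals_squared_paired_t(rng):
    values = rng.normal(10, 2, size=(12, 2))
    table = make_table(values, conditions=("B", "C2"))
    res = condition_anova(table, "x")
    t, p = ss.ttest_rel(values[:, 0], values[:, 1])
    assert res.f_statistic == pytest.approx(t**2, rel=1e-9)
    assert res.p_value == pytest.approx(p, rel=1e-9)
    # with k = 2 the LSD pairwise p equals the omnibus p
    assert res.pairwise["p"].iloc[0] == pytest.approx(p, rel=1e-9)


def _oracle_block_anova(values):
    """From-scratch sums of squares for a complete block design."""
    n, k = values.shape
    grand = values.mean()
    ss_cond = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((values - grand) ** 2).sum()
    ss_res = ss_tot - ss_cond - ss_subj
    df_cond, df_res = k - 1, (n - 1) * (k - 1)
    f = (ss_cond / df_cond) / (ss_res / df_res)
    p = ss_.f.sf(f, df_cond, df_res) if (ss_res > 0) else 0.0
    return f, p, ss_res / df_res, df_res


ss_ = ss  # alias used inside the oracle


def test_anova_matches_sums_of_squares_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(4, 12))
        k = int(rng.integers(2, 5))
        values = rng.normal(0, 1, size=(n, k)) + rng.normal(0, 1, size=(n, 1))
        table = make_table(values, conditions=[f"C{j}" for j in range(k)])
        res = condition_anova(table, "x")
        f, p, ms_res, df_res = _oracle_block_anova(values)
        assert res.f_statistic == pytest.approx(f, abs=1e-8, rel=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.residual_ms == pytest.approx(ms_res, rel=1e-8)
        assert res.df_residual == df_res


def test_lsd_pairwise_equals_pooled_variance_t(rng):
    values = rng.normal(5, 1, size=(10, 3))
    table = make_table(values)
    res = condition_anova(table, "x")
    for pw in res.pairwise.itertuples():
        i = ["B", "C1", "C2"].index(pw.condition_1)
        j = ["B", "C1", "C2"].index(pw.condition_2)
        diff = values[:, i].mean() - values[:, j].mean()
        se = math.sqrt(res.residual_ms * 2 / 10)
        t = diff / se
        p = 2 * ss.t.sf(abs(t), res.df_residual)
        assert pw.t == pytest.approx(t, rel=1e-9)
        assert pw.p == pytest.approx(p, rel=1e-9)


def test_listwise_deletion_and_minimum_subjects(rng):
    values = rng.normal(0, 1, size=(5, 3))
    table = make_table(values)
    df = table.data.drop(index=[0])  # S00 loses its B cell
    table2 = CohortTable(df)
    with pytest.warns(UserWarning):
        res = condition_anova(table2, "x")
    f, _, _, _ = _oracle_block_anova(values[1:])
    assert res.f_statistic == pytest.approx(f, rel=1e-8)
    tiny = make_table(values[:2])
    with pytest.raises(ValueError):
        condition_anova(tiny, "x")


# ------------------------------------------------------------- effect sizes

def test_cohens_d_published_values():
    # sleep latency B vs C1 and N2 B vs C1 at the printed precision
    assert round(cohens_d(8.48, 5.80, 9.89, 5.68, 18).d_corrected, 2) == 0.24
    assert round(cohens_d(232.50, 37.11, 232.89, 33.34, 18).d_corrected, 2) == 0.01


def test_cohens_d_zero_for_equal_means():
    es = cohens_d(5.0, 1.0, 5.0, 2.0, 10)
    assert es.d == 0.0
    assert es.d_corrected == 0.0


def test_cohens_d_validation():
    with pytest.raises(ValueError):
        cohens_d(1.0, 0.0, 2.0, 1.0, 10)
    with pytest.raises(ValueError):
        cohens_d(1.0, 1.0, 2.0, 1.0, 1)


# ------------------------------------------------------------- correlations

def test_pearson_trivial_directions():
    x = np.arange(10.0)
    r, p, sig = pearson_with_bonferroni(x, x, n_tests=4)
    assert r == pytest.approx(1.0)
    assert p < 1e-9 and sig
    r2, _, _ = pearson_with_bonferroni(x, -x, n_tests=4)
    assert r2 == pytest.approx(-1.0)


def test_pearson_zero_variance_undefined():
    r, p, sig = pearson_with_bonferroni([1.0] * 5, [1, 2, 3, 4, 5], n_tests=4)
    assert math.isnan(r) and math.isnan(p) and not sig


# ---------------------------------------------------------------- word-pair

def _sessions(rng, n=10, shift=(0.0, 0.0, 0.0), improvement=6.0, noise=1.0):
    out = []
    for i in range(n):
        base = rng.uniform(15, 30)
        for cond, sh in zip(("B", "C1", "C2"), shift):
            imm = np.clip(round((base + sh + noise * rng.standard_normal()) * 2) / 2,
                          0, 39.5)
            dly = np.clip(round((imm + improvement + noise * rng.standard_normal()) * 2) / 2,
                          0, 39.5)
            out.append(WordPairSession.from_points(f"S{i:02d}", cond, imm, dly))
    return out


def test_wordpair_model_improvement_contrasts(rng):
    sessions = _sessions(rng, improvement=6.7, noise=0.5)
    res = wordpair_model(sessions, "improvement")
    for cond, c in res.extra["improvement_contrasts"].items():
        assert c["mean_improvement"] == pytest.approx(6.7, abs=1.0)
        assert c["p"] < 1e-6


def test_wordpair_model_excludes_flagged_subjects(rng):
    sessions = _sessions(rng)
    flagged = [
        s if s.subject != "S00"
        else WordPairSession(s.subject, s.condition, s.immediate_half_units,
                             s.delayed_half_units, excluded=True)
        for s in sessions
    ]
    res = wordpair_model(flagged, "immediate")
    assert res.extra["improvement_contrasts"]["B"]  # runs
    # 9 subjects remain -> residual df = (9-1)(3-1)
    assert res.df_residual == 16


def test_wordpair_tukey_equals_unadjusted_for_two_conditions(rng):
    out = []
    for i in range(8):
        for cond in ("B", "C2"):
            imm = round(rng.uniform(10, 30) * 2) / 2
            dly = min(imm + round(rng.uniform(0, 10) * 2) / 2, 39.5)
            out.append(WordPairSession.from_points(f"S{i:02d}", cond, imm, dly))
    res = wordpair_model(out, "delayed")
    assert res.pairwise["p"].iloc[0] == pytest.approx(res.p_value, rel=1e-6)
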