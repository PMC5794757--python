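"""Condition-comparison statistics over subject x condition cohort tables.

The omnibus model for every EEG feature is a univariate general linear
model with condition as fixed factor and subject as random (blocking)
factor -- equivalently a two-way ANOVA without interaction on a complete
block design.  Post hoc comparisons are Fisher's least significant
difference (LSD) tests: pairwise t statistics built from the residual
mean square of the omnibus model, with *no* multiplicity adjustment.
That absence of adjustment is the definition of LSD, not an omission.

Effect sizes are pooled-SD Cohen's d with Hedges' small-sample
correction J = 1 - 3/(4*(2n-2) - 1); both raw and corrected values are
reported.  Word-pair measures use the same block ANOVA on non-excluded
subjects with Tukey-adjusted (studentized-range) pairwise p-values.
Pearson correlations between spindle features and recall measures are
two-tailed, flagged at a Bonferroni-corrected alpha (0.05/4 = 0.0125 for
the four recall measures).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as ss
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .wordpair import (
    WordPairSession,
    initial_acquisition_rate,
    overnight_improvement,
)

__all__ = [
    "CohortTable",
    "ComparisonResult",
    "EffectSize",
    "condition_anova",
    "cohens_d",
    "pearson_with_bonferroni",
    "wordpair_model",
]


class CohortTable:
    """Tidy (subject, condition, feature, value) table, complete blocks.

    The container behind every statistical comparison: one scalar value
    per subject x condition x feature cell.
    """

    COLUMNS = ("subject", "condition", "feature", "value")

    def __init__(self, data: pd.DataFrame):
        missing = set(self.COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if data.duplicated(["subject", "condition", "feature"]).any():
            raise ValueError("duplicate subject x condition x feature cells")
        if data["condition"].nunique() < 2:
            raise ValueError("need at least 2 conditions")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "CohortTable":
        return cls(pd.DataFrame(records))

    def features(self) -> List[str]:
        return sorted(self.data["feature"].unique())

    def wide(self, feature: str) -> pd.DataFrame:
        """Subject x condition matrix for one feature (complete rows only).

        Subjects with missing cells are dropped listwise with a warning.
        """
        sub = self.data[self.data["feature"] == feature]
        if sub.empty:
            raise KeyError(f"feature {feature!r} not in table")
        wide = sub.pivot(index="subject", columns="condition", values="value")
        incomplete = wide.isna().any(axis=1)
        if incomplete.any():
            warnings.warn(
                f"dropping {int(incomplete.sum())} subject(s) with missing "
                f"cells for feature {feature!r}"
            )
            wide = wide[~incomplete]
        return wide


@dataclass(frozen=True)
class EffectSize:
    d: float  # pooled-SD Cohen's d, unsigned
    d_corrected: float  # with Hedges' small-sample factor


@dataclass
class ComparisonResult:
    """Omnibus + pairwise results for one feature."""

    feature: str
    f_statistic: float
    p_value: float
    df_condition: int
    df_residual: int
    residual_ms: float
    pairwise: pd.DataFrame  # condition_1, condition_2, mean_diff, t, p, d, d_corrected
    condition_means: pd.Series
    extra: dict = field(default_factory=dict)


def cohens_d(
    mean1: float, sd1: float, mean2: float, sd2: float, n_per_group: int
) -> EffectSize:
    """Pooled-SD Cohen's d with Hedges' small-sample correction.

    d = |mean2 - mean1| / sqrt((sd1^2 + sd2^2)/2);
    J = 1 - 3/(4*(2n - 2) - 1).  Returns both raw and corrected values.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n_per_group <= 1:
        raise ValueError("n_per_group must exceed 1")
    pooled = math.sqrt((sd1**2 + sd2**2) / 2.0)
    d = abs(mean2 - mean1) / pooled
    j = 1.0 - 3.0 / (4.0 * (2 * n_per_group - 2) - 1.0)
    return EffectSize(d=d, d_corrected=d * j)


def _pairwise_frame(
    wide: pd.DataFrame,
    ms_resid: float,
    df_resid: int,
    adjust: str = "lsd",
) -> pd.DataFrame:
    conds = list(wide.columns)
    n = len(wide)
    k = len(conds)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c1, c2 = conds[i], conds[j]
            diff = wide[c1].mean() - wide[c2].mean()
            se = math.sqrt(ms_resid * 2.0 / n)
            if se > 0:
                t = diff / se
            else:
                t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
            if adjust == "lsd":
                p = 2.0 * ss.t.sf(abs(t), df_resid) if np.isfinite(t) else 0.0
            elif adjust == "tukey":
                q = abs(t) * math.sqrt(2.0)
                p = float(ss.studentized_range.sf(q, k, df_resid))
            else:
                raise ValueError(f"unknown adjustment {adjust!r}")
            if ms_resid == 0:
                p = 1.0 if diff == 0 else 0.0
            eff = cohens_d(
                wide[c2].mean(), max(wide[c2].std(ddof=1), 1e-12),
                wide[c1].mean(), max(wide[c1].std(ddof=1), 1e-12),
                n,
            )
            rows.append(
                {
                    "condition_1": c1,
                    "condition_2": c2,
                    "mean_diff": diff,
                    "t": t,
                    "p": min(p, 1.0),
                    "d": eff.d,
                    "d_corrected": eff.d_corrected,
                }
            )
    return pd.DataFrame(rows)


def condition_anova(
    table: CohortTable, feature: str, posthoc: str = "lsd"
) -> ComparisonResult:
    """Block ANOVA (condition fixed, subject random) with LSD post hocs.

    The design is balanced after listwise removal of incomplete subjects,
    so Type I/III sums of squares coincide.  Pairwise tests reuse the
    residual mean square and its degrees of freedom; ``posthoc`` selects
    the LSD (unadjusted) or Tukey (studentized range) p-value.
    """
    wide = table.wide(feature)
    if len(wide) < 3:
        raise ValueError("need at least 3 complete subjects")
    long = wide.reset_index().melt(
        id_vars="subject", var_name="condition", value_name="value"
    )
    if long["value"].var(ddof=0) == 0:
        # Degenerate: all values identical -> F = 0, p = 1.
        ms_resid, df_resid = 0.0, (len(wide) - 1) * (wide.shape[1] - 1)
        pairwise = _pairwise_frame(wide, 0.0, df_resid, posthoc)
        return ComparisonResult(
            feature=feature,
            f_statistic=0.0,
            p_value=1.0,
            df_condition=wide.shape[1] - 1,
            df_residual=df_resid,
            residual_ms=0.0,
            pairwise=pairwise,
            condition_means=wide.mean(),
        )
    model = smf.ols("value ~ C(condition) + C(subject)", data=long).fit()
    av = sm.stats.anova_lm(model, typ=2)
    f = float(av.loc["C(condition)", "F"])
    p = float(av.loc["C(condition)", "PR(>F)"])
    df_cond = int(av.loc["C(condition)", "df"])
    df_resid = int(av.loc["Residual", "df"])
    ms_resid = float(av.loc["Residual", "sum_sq"] / av.loc["Residual", "df"])
    pairwise = _pairwise_frame(wide, ms_resid, df_resid, posthoc)
    return ComparisonResult(
        feature=feature,
        f_statistic=f,
        p_value=p,
        df_condition=df_cond,
        df_residual=df_resid,
        residual_ms=ms_resid,
        pairwise=pairwise,
        condition_means=wide.mean(),
    )


def pearson_with_bonferroni(
    x: Sequence[float], y: Sequence[float], n_tests: int
) -> Tuple[float, float, bool]:
    """Two-tailed Pearson correlation with a Bonferroni significance flag.

    Returns ``(r, p_raw, significant)`` where the flag tests the raw p
    against alpha = 0.05 / n_tests (0.0125 for the study's four recall
    measures).  Zero-variance input yields ``(nan, nan, False)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        return math.nan, math.nan, False
    r, p = ss.pearsonr(x, y)
    alpha = 0.05 / n_tests
    return float(r), float(p), bool(p <= alpha)


_WORDPAIR_FEATURES = {
    "improvement": overnight_improvement,
    "immediate": lambda s: s.immediate_score,
    "delayed": lambda s: s.delayed_score,
    "acquisition": initial_acquisition_rate,
}


def wordpair_model(
    sessions: Sequence[WordPairSession], feature: str = "improvement"
) -> ComparisonResult:
    """Condition comparison of a word-pair measure with Tukey post hocs.

    Runs the block ANOVA on non-excluded subjects only.  ``extra``
    carries per-condition paired contrasts of delayed vs immediate recall
    (t, p), the study's within-condition overnight-improvement test.
    """
    if feature not in _WORDPAIR_FEATURES:
        raise ValueError(f"feature must be one of {sorted(_WORDPAIR_FEATURES)}")
    fn = _WORDPAIR_FEATURES[feature]
    kept = [s for s in sessions if not s.excluded]
    if len({s.subject for s in kept}) < 3:
        raise ValueError("need at least 3 non-excluded subjects")
    table = CohortTable.from_records(
        {
            "subject": s.subject,
            "condition": s.condition,
            "feature": feature,
            "value": fn(s),
        }
        for s in kept
    )
    result = condition_anova(table, feature, posthoc="tukey")

    contrasts = {}
    by_cond: Dict[str, List[WordPairSession]] = {}
    for s in kept:
        by_cond.setdefault(s.condition, []).append(s)
    for cond, group in sorted(by_cond.items()):
        imm = np.array([g.immediate_score for g in group])
        dly = np.array([g.delayed_score for g in group])
        diff = dly - imm
        if np.allclose(diff.std(ddof=1), 0):
            t, p = (math.inf, 0.0) if diff.mean() != 0 else (0.0, 1.0)
        else:
            t, p = ss.ttest_rel(dly, imm)
        contrasts[cond] = {"mean_improvement": float(diff.mean()),
                           "t": float(t), "p": float(p)}
    result.extra["improvement_contrasts"] = contrasts
    return result
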