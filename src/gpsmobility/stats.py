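"""Validation statistics: correlations with Bonferroni control, one-way
ANOVA with a Welch fallback and eta-squared, and chi-square contingency
tests.

Correlation coefficients with |r| > 0.3 are flagged "meaningful" (a
moderate effect at small n, regardless of significance); a second flag marks
coefficients surviving the Bonferroni-corrected alpha for the feature family
(.05/13 = .0038 for the 13 daily GPS features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

MEANINGFUL_R = 0.3
N_GPS_FEATURES = 13


@dataclass
class CorrelationResult:
    feature: str
    validator: str
    method: str
    r: float
    p: float
    n: int
    meaningful: bool
    survives_bonferroni: bool


@dataclass
class AnovaResult:
    factor: str
    feature: str
    F: float
    df1: float
    df2: float
    p: float
    eta_squared: float
    welch_used: bool
    posthoc: list = field(default_factory=list)  # (group_a, group_b, p_adj)


def bonferroni_alpha(family_alpha, m_tests):
    """Per-test threshold alpha/m (e.g. .05/13 -> .0038, .05/17 -> .0029)."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return family_alpha / m_tests


def correlate(x, y, method="pearson", feature="x", validator="y",
              family_alpha=0.05, m_tests=N_GPS_FEATURES,
              meaningful_r=MEANINGFUL_R):
    """Pearson or Spearman correlation with pairwise deletion of missing
    pairs and a two-tailed p-value.

    Returns a :class:`CorrelationResult`; r is NaN (flags False) when either
    vector has zero variance or fewer than 3 complete pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    alpha = bonferroni_alpha(family_alpha, m_tests)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(feature, validator, method, np.nan, np.nan,
                                 n, False, False)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(feature, validator, method, float(r), float(p),
                             n, bool(abs(r) > meaningful_r), bool(p < alpha))


def welch_anova(groups, labels=None, factor="factor", feature="feature",
                levene_alpha=0.05):
    """One-way ANOVA with a Welch test when group variances are unequal.

    A Levene pre-test (p < ``levene_alpha``) triggers the Welch F with
    Satterthwaite degrees of freedom (via pingouin); otherwise the classical
    one-way F is reported.  eta-squared always comes from the classical
    SS_between/SS_total decomposition.  Pairwise Welch t tests with
    Bonferroni-adjusted p complete the result.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for lab, g in zip(labels, groups):
        if len(g) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")

    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = float(((allv - grand) ** 2).sum())
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    if ss_total == 0.0:  # all values identical in every group
        ncomp = len(groups) * (len(groups) - 1) // 2
        posthoc = [(labels[i], labels[j], 1.0)
                   for i in range(len(groups)) for j in range(i + 1, len(groups))]
        return AnovaResult(factor, feature, 0.0, float(len(groups) - 1),
                           float(len(allv) - len(groups)), 1.0, 0.0, False,
                           posthoc)

    variances = [g.var(ddof=1) for g in groups]
    if all(v == 0 for v in variances):
        heteroskedastic = False
    else:
        _, lev_p = sps.levene(*groups, center="median")
        heteroskedastic = bool(lev_p < levene_alpha)

    if heteroskedastic:
        import pingouin as pg
        df = pd.DataFrame({
            "value": allv,
            "group": np.repeat(labels, [len(g) for g in groups]),
        })
        aov = pg.welch_anova(data=df, dv="value", between="group")
        F = float(aov["F"].iloc[0])
        df1 = float(aov["ddof1"].iloc[0])
        df2 = float(aov["ddof2"].iloc[0])
        p = float(aov["p_unc"].iloc[0])
    else:
        F, p = sps.f_oneway(*groups)
        F, p = float(F), float(p)
        df1 = float(len(groups) - 1)
        df2 = float(len(allv) - len(groups))

    ncomp = len(groups) * (len(groups) - 1) // 2
    posthoc = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            _, pp = sps.ttest_ind(groups[i], groups[j], equal_var=False)
            posthoc.append((labels[i], labels[j], float(min(pp * ncomp, 1.0))))
    return AnovaResult(factor, feature, F, df1, df2, p, float(eta2),
                       heteroskedastic, posthoc)


def chi_square(table):
    """Pearson chi-square of an r x c count table, no continuity correction.

    Returns ``(statistic, df, p)``; raises on negative counts, tables smaller
    than 2x2, or a zero row/column marginal.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(T < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(T.sum(axis=0) == 0) or np.any(T.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    stat, p, df, _ = sps.chi2_contingency(T, correction=False)
    return float(stat), int(df), float(p)


def correlation_table(summary_df, validators_df, feature_cols, validator_cols,
                      method="pearson", family_alpha=0.05, m_tests=None):
    """Feature x validator correlation surface.

    ``summary_df`` and ``validators_df`` are joined on participant_id; each
    feature column is tested against each validator column with pairwise
    deletion.  ``m_tests`` defaults to the number of feature columns (one
    Bonferroni family per validator, matching a 13-feature family of .0038).
    Returns a long DataFrame of :class:`CorrelationResult` fields.
    """
    if m_tests is None:
        m_tests = len(feature_cols)
    merged = summary_df.merge(validators_df, on="participant_id", how="inner")
    rows = []
    for v in validator_cols:
        for f in feature_cols:
            res = correlate(merged[f], merged[v], method=method, feature=f,
                            validator=v, family_alpha=family_alpha,
                            m_tests=m_tests)
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
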