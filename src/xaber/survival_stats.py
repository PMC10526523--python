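"""Survival evaluation and cohort comparison statistics.

Signature scores and group labels are evaluated with Kaplan-Meier curves,
the two-group log-rank test, and Cox proportional-hazards models (Efron
handling of tied event times).  Follow-up is administratively censored at
a configurable horizon (20 years for signature evaluation, 5 for subtype
comparisons).  The module also wraps the cross-tab percentage / chi-square
and rank-based comparisons used throughout the cohort analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

SPLIT_HIGH = "high"
SPLIT_LOW = "low"


def apply_horizon(time, event, horizon_years: float | None):
    """Administratively censor follow-up at the horizon."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if horizon_years is None:
        return t, e
    e = e & (t <= horizon_years)
    t = np.minimum(t, horizon_years)
    return t, e


def median_split(scores: pd.Series) -> pd.Series:
    """Partition samples at the median score; ties go to ``low``."""
    s = pd.Series(scores)
    if len(s) < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(s.median())
    if (s == s.iloc[0]).all():
        raise ValueError("all scores identical; no median split possible")
    out = pd.Series(np.where(s > med, SPLIT_HIGH, SPLIT_LOW), index=s.index)
    out.name = "split"
    return out


def km_logrank(
    time, event, groups: pd.Series, horizon_years: float | None = None
):
    """Kaplan-Meier curves per group plus the log-rank test.

    Returns ``(curves, statistic, p)`` where ``curves`` maps group name to
    a survival-function DataFrame (time, at-risk, survival).
    """
    t, e = apply_horizon(time, event, horizon_years)
    g = pd.Series(groups).reset_index(drop=True)
    if g.value_counts().min() < 1 or g.nunique() < 2:
        raise ValueError("need at least two non-empty groups")
    if not e.any():
        raise ValueError("no events observed; log-rank test undefined")
    curves = {}
    for name in g.unique():
        mask = (g == name).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=str(name))
        tbl = kmf.event_table
        curves[name] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "at_risk": tbl["at_risk"].to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            }
        )
    res = multivariate_logrank_test(t, g.to_numpy(), e)
    return curves, float(res.test_statistic), float(res.p_value)


def cox_hr(
    time,
    event,
    score: pd.Series,
    horizon_years: float | None = 20.0,
) -> dict:
    """Cox proportional-hazards fit of survival on a signature score.

    Returns the per-unit-score hazard ratio with 95% CI and p, and the
    hazard ratio for the median-split binary factor alongside.  Monotone
    likelihood (perfect separation) is flagged with an unbounded CI.
    """
    s = pd.Series(score).astype(float)
    if s.nunique() <= 1:
        raise ValueError("score is constant; Cox model undefined")
    t, e = apply_horizon(time, event, horizon_years)
    if not e.any():
        raise ValueError("no events observed within the horizon")

    def _fit(covariate: np.ndarray) -> dict:
        df = pd.DataFrame({"time": t, "event": e.astype(int), "x": covariate})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except Exception as err:  # monotone likelihood / separation
            return {
                "hr": float("inf"),
                "ci_low": 0.0,
                "ci_high": float("inf"),
                "p": float("nan"),
                "flagged": True,
                "note": f"fit failed: {err}",
            }
        beta = float(cph.params_["x"])
        se = float(cph.standard_errors_["x"])
        flagged = not np.isfinite(se) or se > 50
        return {
            "hr": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
            "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
            "p": float(cph.summary.loc["x", "p"]),
            "flagged": flagged,
        }

    continuous = _fit(s.to_numpy())
    split = median_split(s)
    binary = _fit((split == SPLIT_HIGH).to_numpy(float))
    return {"per_unit": continuous, "median_split": binary, "n": int(len(s)),
            "n_events": int(e.sum())}


def crosstab_percent(numerators, denominators):
    """Integer percentages per category plus a chi-square across categories.

    ``numerators[i] / denominators[i]`` is reported as a round-half-up
    percentage; Pearson's chi-square (no continuity correction) is run on
    the implied 2 x k table [[num], [den - num]].
    """
    num = np.asarray(numerators, dtype=np.int64)
    den = np.asarray(denominators, dtype=np.int64)
    if num.shape != den.shape or num.ndim != 1:
        raise ValueError("numerators and denominators must be aligned 1-D")
    if np.any(den <= 0):
        raise ValueError("denominators must be positive")
    if np.any(num > den) or np.any(num < 0):
        raise ValueError("need 0 <= numerator <= denominator per category")
    percents = np.floor(100.0 * num / den + 0.5).astype(int)
    if len(num) >= 2:
        table = np.vstack([num, den - num])
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        else:
            chi2, p = float("nan"), float("nan")
    else:
        chi2, p = float("nan"), float("nan")
    return percents, float(chi2), float(p)


def rank_tests(values, labels, kind: str):
    """Rank-based group comparison: Wilcoxon rank-sum or Kruskal-Wallis.

    ``kind='wilcoxon'`` requires exactly two groups (Mann-Whitney U with
    tie correction, two-sided); ``kind='kruskal_wallis'`` takes two or
    more.  Returns (statistic, p).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = [v[lab == g] for g in pd.unique(lab)]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if kind == "wilcoxon":
        if len(groups) != 2:
            raise ValueError("wilcoxon requires exactly two groups")
        stat, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    elif kind == "kruskal_wallis":
        if len(groups) < 2:
            raise ValueError("kruskal_wallis requires at least two groups")
        stat, p = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return float(stat), float(p)
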