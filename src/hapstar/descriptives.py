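"""Descriptive statistics for 2x2 exposure tables and cohort summaries.

These are the bivariate analyses run before any regression modelling:
prevalence ratios (PR, Katz log interval) for binary characteristics across
the clean/unclean cooking-fuel columns, odds ratios (OR, Woolf log interval)
for mother-level categorical characteristics against a reference level,
Pearson chi-square or Fisher exact association tests, and a Welch t-test
for mother's age. A report generator assembles a Table-1-style CSV from a
cohort, applying the row-appropriate estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "RatioEstimate",
    "TestResult",
    "prevalence_ratio",
    "odds_ratio",
    "pearson_chi_square",
    "fisher_exact",
    "association_test",
    "welch_t_test",
    "table1_report",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = characteristic present/absent, cols = unclean/clean.

    Layout::

                     unclean   clean
        present         a        c
        absent          b        d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.c], [self.b, self.d]], dtype=float)

    def swap_exposure(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class RatioEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    kind: str = "prevalence_ratio"

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("require 0 < ci_low <= estimate <= ci_high")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0,1]")


def prevalence_ratio(
    table: ContingencyTable2x2, level: float = 0.95
) -> RatioEstimate:
    """Prevalence ratio of the characteristic, unclean vs clean exposure.

    PR = [a/(a+b)] / [c/(c+d)], with the Katz log interval
    exp(ln PR +/- z * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))). No continuity
    correction: a zero numerator cell is an error, not a corrected estimate.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("both exposure columns need nonzero totals")
    if a == 0 or c == 0:
        raise ValueError("undefined PR: zero numerator cell")
    pr = (a / (a + b)) / (c / (c + d))
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return RatioEstimate(
        estimate=pr,
        ci_low=pr * np.exp(-z * se),
        ci_high=pr * np.exp(z * se),
        level=level,
        kind="prevalence_ratio",
    )


def odds_ratio(table: ContingencyTable2x2, level: float = 0.95) -> RatioEstimate:
    """Odds ratio of unclean exposure, category vs reference.

    With a = unclean & category, b = clean & category, c = unclean &
    reference, d = clean & reference: OR = (a*d)/(b*c) with the Woolf log
    interval exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)). Zero cells are
    an error (no Haldane correction).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        raise ValueError("odds ratio undefined with a zero cell")
    orr = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RatioEstimate(
        estimate=orr,
        ci_low=orr * np.exp(-z * se),
        ci_high=orr * np.exp(z * se),
        level=level,
        kind="odds_ratio",
    )


def pearson_chi_square(table: np.ndarray | list) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("table total must be positive")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero row or column margin")
    res = stats.chi2_contingency(obs, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.dof),
        method="pearson_chi_square",
    )


def fisher_exact(table: ContingencyTable2x2 | np.ndarray) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table."""
    if isinstance(table, ContingencyTable2x2):
        obs = table.as_array()
    else:
        obs = np.asarray(table, dtype=float)
    _, p = stats.fisher_exact(obs, alternative="two-sided")
    return TestResult(statistic=float("nan"), p_value=float(p), df=0.0,
                      method="fisher_exact")


def expected_counts(table: np.ndarray | list) -> np.ndarray:
    obs = np.asarray(table, dtype=float)
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()


def association_test(table: np.ndarray | list) -> TestResult:
    """Pearson chi-square, switching to Fisher when any expected cell < 5.

    The Fisher fallback only applies to 2x2 tables; larger sparse tables
    keep the chi-square with its asymptotic caveat.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape == (2, 2) and np.any(expected_counts(obs) < 5):
        return fisher_exact(obs)
    return pearson_chi_square(obs)


def welch_t_test(x, y) -> TestResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      df=float(res.df), method="welch_t")


def _pr_row(characteristic, level, a, b, c, d):
    tab = ContingencyTable2x2(a, b, c, d)
    try:
        est = prevalence_ratio(tab)
        e, lo, hi = est.estimate, est.ci_low, est.ci_high
    except ValueError:  # zero cell: report counts, leave ratio blank
        e = lo = hi = np.nan
    p = association_test(tab.as_array()).p_value
    return dict(characteristic=characteristic, level=level,
                n_overall=a + c, n_clean=c, n_unclean=a,
                estimate=e, ci_low=lo, ci_high=hi,
                estimator_kind="prevalence_ratio", p_value=p)


def table1_report(
    births: pd.DataFrame, out_csv: str | Path | None = None,
    reference: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble a Table-1-style summary from a cohort of birth records.

    Binary birth-level rows (stillbirth, low birth weight, preterm) and the
    smoking row use the prevalence ratio across fuel columns; mother-level
    categorical rows (education, wealth, region) use odds ratios against a
    reference level (default: first category / first region). Mother-level
    rows are computed on one record per mother.
    """
    reference = reference or {}
    mothers = births.drop_duplicates("mother_id")
    unclean = births["fuel_unclean"] == 1
    rows = []

    for name, col in (("birth_status", "outcome_stillbirth"),
                      ("birth_weight", "outcome_lbw"),
                      ("pregnancy_duration", "outcome_preterm")):
        sub = births[births[col].notna()]
        y = sub[col] == 1
        e = sub["fuel_unclean"] == 1
        a, b = int((y & e).sum()), int((~y & e).sum())
        c, d = int((y & ~e).sum()), int((~y & ~e).sum())
        rows.append(_pr_row(name, "present", a, b, c, d))

    ms = mothers["smoker"] == 1
    me = mothers["fuel_unclean"] == 1
    rows.append(_pr_row("smoking", "smoker",
                        int((ms & me).sum()), int((~ms & me).sum()),
                        int((ms & ~me).sum()), int((~ms & ~me).sum())))

    for name in ("education", "wealth", "region"):
        series = mothers[name].astype(str)
        levels = [str(lv) for lv in
                  (mothers[name].cat.categories
                   if isinstance(mothers[name].dtype, pd.CategoricalDtype)
                   else sorted(series.unique()))]
        ref = reference.get(name, levels[0])
        e = mothers["fuel_unclean"] == 1
        c_ref = int(((series == ref) & e).sum())
        d_ref = int(((series == ref) & ~e).sum())
        ct = pd.crosstab(series, e)
        p = association_test(ct.to_numpy()).p_value
        for lv in levels:
            if lv == ref:
                rows.append(dict(characteristic=name, level=f"{lv} (ref)",
                                 n_overall=int((series == lv).sum()),
                                 n_clean=d_ref, n_unclean=c_ref,
                                 estimate=np.nan, ci_low=np.nan,
                                 ci_high=np.nan, estimator_kind="odds_ratio",
                                 p_value=p))
                continue
            a = int(((series == lv) & e).sum())
            b = int(((series == lv) & ~e).sum())
            try:
                est = odds_ratio(ContingencyTable2x2(a, b, c_ref, d_ref))
                e_, lo, hi = est.estimate, est.ci_low, est.ci_high
            except ValueError:  # zero cell
                e_ = lo = hi = np.nan
            rows.append(dict(characteristic=name, level=lv,
                             n_overall=a + b, n_clean=b, n_unclean=a,
                             estimate=e_, ci_low=lo, ci_high=hi,
                             estimator_kind="odds_ratio", p_value=p))

    out = pd.DataFrame(rows)
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out
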