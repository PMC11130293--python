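"""Stratified statistics: decile regressions and rich/poor comparisons.

Given per-comuna records carrying an income decile and an outcome (mean
mobility reduction, emigration percentage, ...), this module fits the
simple linear regression of the outcome on the decile and compares the
richest fraction of the decile distribution against the rest with a
two-sample t-test (Welch by default; the pooled-variance variant is a
flag). The rich stratum is the top ``rich_fraction`` of the decile
covariate (deciles 9-10 at the default 0.2 on a 1-10 scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RegressionSummary", "TTestReport", "decile_outcome_regression",
           "slope_confidence_interval", "rich_poor_ttest"]


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r: float          # Pearson correlation
    r_squared: float  # equals r**2 for the simple regression
    slope_stderr: float
    intercept_stderr: float
    p_value: float
    n: int


@dataclass
class TTestReport:
    t: float
    df: float
    p_value: float
    rich_mean: float
    poor_mean: float
    n_rich: int
    n_poor: int
    decile_cut: float


def decile_outcome_regression(records: pd.DataFrame,
                              outcome: str,
                              decile_col: str = "income_decile"
                              ) -> RegressionSummary:
    """OLS of *outcome* on the income decile, with Pearson r and R^2.

    Requires at least 3 complete records; a constant outcome has no defined
    correlation and comes back with NaN r/R^2/p.
    """
    data = records[[decile_col, outcome]].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 records for the decile regression")
    x = data[decile_col].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        slope = 0.0 if np.ptp(y) == 0 else np.nan
        return RegressionSummary(slope, float(y.mean()), np.nan, np.nan,
                                 np.nan, np.nan, np.nan, len(data))
    fit = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r=float(fit.rvalue), r_squared=float(fit.rvalue ** 2),
        slope_stderr=float(fit.stderr),
        intercept_stderr=float(fit.intercept_stderr),
        p_value=float(fit.pvalue), n=len(data))


def slope_confidence_interval(summary: RegressionSummary,
                              alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided (1-alpha) confidence interval for the regression slope."""
    tcrit = stats.t.ppf(1 - alpha / 2, summary.n - 2)
    half = tcrit * summary.slope_stderr
    return summary.slope - half, summary.slope + half


def rich_poor_ttest(records: pd.DataFrame, outcome: str,
                    rich_fraction: float = 0.2,
                    decile_col: str = "income_decile",
                    equal_var: bool = False) -> TTestReport:
    """Two-sample t-test of the outcome between richest and poorest strata.

    The rich stratum holds records at or above the (1 - rich_fraction)
    quantile of the decile covariate; both strata need at least 2 records.
    Welch's unequal-variance statistic by default.
    """
    data = records[[decile_col, outcome]].dropna()
    cut = float(data[decile_col].quantile(1.0 - rich_fraction))
    rich = data.loc[data[decile_col] >= cut, outcome].to_numpy(dtype=float)
    poor = data.loc[data[decile_col] < cut, outcome].to_numpy(dtype=float)
    if len(rich) < 2 or len(poor) < 2:
        raise ValueError("each stratum needs at least 2 records")
    res = stats.ttest_ind(rich, poor, equal_var=equal_var)
    return TTestReport(
        t=float(res.statistic), df=float(res.df), p_value=float(res.pvalue),
        rich_mean=float(rich.mean()), poor_mean=float(poor.mean()),
        n_rich=len(rich), n_poor=len(poor), decile_cut=cut)
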