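"""Equity statistics for service-area summaries.

Fits ordinary least squares to the natural log of catchment population,
with the catchment's median deprivation decile and/or log area as
predictors; converts log-scale coefficients to percent changes; and runs
a Spearman rank-correlation sensitivity analysis.

All logs are natural: a coefficient β maps to a (e^β − 1)·100% change in
population per unit predictor, so β = −0.20 reads as an 18% decrease.
95% confidence intervals use the t distribution with residual degrees of
freedom. Both plain and adjusted R² are reported; the adjusted value can
be negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .aggregate import ServiceAreaSummary
from .errors import ConfigurationError, ValidationError

PREDICTORS = ("median_decile", "log_area")


@dataclass(frozen=True)
class Estimate:
    """One fitted coefficient with its t-based 95% CI and p-value."""

    coef: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    predictors: dict[str, Estimate]
    intercept: Estimate
    n: int
    df_residual: int
    r2: float
    r2_adjusted: float
    f_statistic: float
    f_df: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "df_residual": self.df_residual,
            "r2": self.r2,
            "r2_adjusted": self.r2_adjusted,
            "f_statistic": self.f_statistic,
            "f_df": list(self.f_df),
            "intercept": self.intercept.__dict__,
            "predictors": {k: v.__dict__ for k, v in self.predictors.items()},
        }


@dataclass(frozen=True)
class PercentChange:
    """Percent change in population per +1 predictor unit.

    ``percent = (1 − e^β)·100``: positive values are decreases. The CI
    bounds swap under this decreasing transform, so ``ci_low_pct`` comes
    from the coefficient CI's upper bound and vice versa.
    """

    percent: float
    ci_low_pct: float
    ci_high_pct: float

    @property
    def rounded(self) -> tuple[int, int, int]:
        """(percent, ci_low, ci_high) rounded to the nearest integer percent."""
        return (
            int(round(self.percent)),
            int(round(self.ci_low_pct)),
            int(round(self.ci_high_pct)),
        )


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def _design(
    summaries: Sequence[ServiceAreaSummary], predictors: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    for s in summaries:
        if s.total_population <= 0:
            raise ValidationError(
                f"resource {s.resource_id!r} has non-positive population; cannot log-transform"
            )
        if s.total_area_km2 <= 0:
            raise ValidationError(
                f"resource {s.resource_id!r} has non-positive area; cannot log-transform"
            )
    y = np.log([s.total_population for s in summaries])
    cols = []
    for p in predictors:
        if p == "median_decile":
            cols.append([s.median_decile for s in summaries])
        elif p == "log_area":
            cols.append([math.log(s.total_area_km2) for s in summaries])
        else:
            raise ConfigurationError(f"unknown predictor {p!r}; choose from {PREDICTORS}")
    X = np.column_stack(cols)
    return y, X


def fit_loglinear(
    summaries: Sequence[ServiceAreaSummary],
    predictors: Sequence[str] = ("median_decile",),
) -> RegressionResult:
    """OLS of ln(total_population) on the chosen predictors.

    ``predictors`` is any non-empty subset of ``("median_decile",
    "log_area")``; area enters as ln(total_area_km2).
    """
    if not predictors:
        raise ConfigurationError("at least one predictor required")
    n = len(summaries)
    p = len(predictors)
    if n <= p + 1:
        raise ConfigurationError(f"need n > {p + 1} rows for {p} predictor(s); got {n}")
    y, X = _design(summaries, predictors)
    for j, name in enumerate(predictors):
        if np.ptp(X[:, j]) == 0:
            raise ConfigurationError(f"predictor {name!r} is constant; design is singular")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ConfigurationError("singular design matrix (collinear predictors)")
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=0.05)

    def est(i: int) -> Estimate:
        return Estimate(
            coef=float(fit.params[i]),
            se=float(fit.bse[i]),
            ci_low=float(ci[i, 0]),
            ci_high=float(ci[i, 1]),
            p_value=float(fit.pvalues[i]),
        )

    return RegressionResult(
        predictors={name: est(j + 1) for j, name in enumerate(predictors)},
        intercept=est(0),
        n=n,
        df_residual=int(fit.df_resid),
        r2=float(fit.rsquared),
        r2_adjusted=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_df=(int(fit.df_model), int(fit.df_resid)),
    )


def percent_change(coef: float, ci_low: float, ci_high: float) -> PercentChange:
    """Convert a natural-log-scale coefficient and CI to percent decrease."""
    if ci_low > ci_high:
        raise ValidationError(f"ci_low {ci_low} exceeds ci_high {ci_high}")
    return PercentChange(
        percent=(1.0 - math.exp(coef)) * 100.0,
        ci_low_pct=(1.0 - math.exp(ci_high)) * 100.0,
        ci_high_pct=(1.0 - math.exp(ci_low)) * 100.0,
    )


def coef_to_percent(result: RegressionResult, predictor: str) -> PercentChange:
    """Percent-change reading of one predictor's coefficient in ``result``."""
    if predictor not in result.predictors:
        raise ConfigurationError(
            f"predictor {predictor!r} not in result (has {sorted(result.predictors)})"
        )
    e = result.predictors[predictor]
    return percent_change(e.coef, e.ci_low, e.ci_high)


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rank correlation with average ranks for ties.

    The p-value uses the t approximation on n − 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if n < 4:
        raise ValidationError(f"need at least 4 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Spearman correlation undefined for a constant vector")
    rho, _ = stats.spearmanr(x, y)
    rho = float(rho)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=p, n=n)
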