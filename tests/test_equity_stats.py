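import math

import numpy as np
import pytest
from scipy import stats

from equicatch.aggregate import ServiceAreaSummary
from equicatch.equity_stats import (
    coef_to_percent,
    fit_loglinear,
    percent_change,
    spearman,
)
from equicatch.errors import ConfigurationError, ValidationError

from .conftest import random_summaries


def summaries_from_xy(x, y):
    """Rows whose ln(population) is y and median_decile is x."""
    return [
        ServiceAreaSummary(f"R{i:03d}", 1, math.exp(yi), 100.0, xi)
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


def normal_equations_oracle(X, y):
    """Explicit matrix-algebra OLS: coefficients and standard errors."""
    Xc = np.column_stack([np.ones(len(y)), X])
    xtx_inv = np.linalg.inv(Xc.T @ Xc)
    beta = xtx_inv @ Xc.T @ y
    resid = y - Xc @ beta
    df = len(y) - Xc.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta, se


def rank_then_pearson_oracle(x, y):
    """Spearman by definition: average ranks, then Pearson correlation."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


class TestFitLoglinear:
    def test_exact_linear_data(self):
        x = np.arange(1.0, 11.0)
        y = 2.0 - 0.5 * x
        res = fit_loglinear(summaries_from_xy(x, y), ["median_decile"])
        est = res.predictors["median_decile"]
        assert est.coef == pytest.approx(-0.5, abs=1e-10)
        assert est.se == pytest.approx(0.0, abs=1e-10)
        assert res.r2_adjusted == pytest.approx(1.0, abs=1e-10)
        assert res.intercept.coef == pytest.approx(2.0, abs=1e-10)

    def test_f_r2adj_identity_at_reported_f(self):
        # Arithmetic check of the identity at F = 4.48 on (1, 36) df
        f, df2, n = 4.48, 36, 38
        r2 = f / (f + df2)
        r2_adj = 1 - (1 - r2) * (n - 1) / df2
        assert round(r2_adj, 3) == 0.086

    def test_f_r2adj_identity_on_fits(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            x = rng.uniform(1, 10, n)
            y = rng.normal(2 - 0.2 * x, 0.5)
            res = fit_loglinear(summaries_from_xy(x, y), ["median_decile"])
            df2 = res.f_df[1]
            lhs = res.r2_adjusted
            rhs = 1 - (1 - res.f_statistic / (res.f_statistic + df2)) * (res.n - 1) / df2
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_normal_equations_oracle_univariate(self):
        rng = np.random.default_rng(101)
        for _ in range(50):
            n = int(rng.integers(8, 50))
            x = rng.uniform(1, 10, n)
            y = rng.normal(12 - 0.2 * x, 0.8)
            res = fit_loglinear(summaries_from_xy(x, y), ["median_decile"])
            beta, se = normal_equations_oracle(x[:, None], y)
            assert res.intercept.coef == pytest.approx(beta[0], abs=1e-8)
            assert res.predictors["median_decile"].coef == pytest.approx(beta[1], abs=1e-8)
            assert res.predictors["median_decile"].se == pytest.approx(se[1], abs=1e-8)

    def test_normal_equations_oracle_multivariate_38_rows(self):
        rng = np.random.default_rng(59)
        for _ in range(60):
            n = 38
            ss = random_summaries(rng, n)
            res = fit_loglinear(ss, ["median_decile", "log_area"])
            X = np.column_stack(
                [[s.median_decile for s in ss], np.log([s.total_area_km2 for s in ss])]
            )
            y = np.log([s.total_population for s in ss])
            beta, se = normal_equations_oracle(X, y)
            assert res.predictors["median_decile"].coef == pytest.approx(beta[1], abs=1e-8)
            assert res.predictors["log_area"].coef == pytest.approx(beta[2], abs=1e-8)
            assert res.predictors["median_decile"].se == pytest.approx(se[1], abs=1e-8)
            assert res.predictors["log_area"].se == pytest.approx(se[2], abs=1e-8)
            assert res.df_residual == n - 3

    def test_ci_p_coherence(self):
        rng = np.random.default_rng(61)
        for _ in range(50):
            n = int(rng.integers(8, 60))
            x = rng.uniform(1, 10, n)
            y = rng.normal(-0.1 * x, rng.uniform(0.2, 2.0))
            est = fit_loglinear(summaries_from_xy(x, y), ["median_decile"]).predictors[
                "median_decile"
            ]
            excludes_zero = est.ci_low > 0 or est.ci_high < 0
            assert (est.p_value < 0.05) == excludes_zero
            assert est.ci_low <= est.coef <= est.ci_high

    def test_ci_uses_t_distribution(self):
        rng = np.random.default_rng(67)
        n = 12
        x = rng.uniform(1, 10, n)
        y = rng.normal(1 - 0.3 * x, 0.7)
        est = fit_loglinear(summaries_from_xy(x, y), ["median_decile"]).predictors[
            "median_decile"
        ]
        tcrit = stats.t.ppf(0.975, n - 2)
        assert est.ci_high - est.coef == pytest.approx(tcrit * est.se, rel=1e-9)

    def test_zero_population_row_named(self):
        ss = random_summaries(np.random.default_rng(1), 10)
        bad = ServiceAreaSummary("RBAD", 1, 0.0, 10.0, 5.0)
        with pytest.raises(ValidationError, match="RBAD"):
            fit_loglinear(ss + [bad], ["median_decile"])

    def test_constant_predictor_rejected(self):
        ss = [ServiceAreaSummary(f"R{i}", 1, 1000.0 + i, 10.0, 5.0) for i in range(10)]
        with pytest.raises(ConfigurationError, match="constant"):
            fit_loglinear(ss, ["median_decile"])

    def test_too_few_rows_rejected(self):
        ss = random_summaries(np.random.default_rng(2), 2)
        with pytest.raises(ConfigurationError):
            fit_loglinear(ss, ["median_decile"])

    def test_unknown_predictor_rejected(self):
        ss = random_summaries(np.random.default_rng(3), 10)
        with pytest.raises(ConfigurationError, match="population_density"):
            fit_loglinear(ss, ["population_density"])


class TestPercentChange:
    def test_beta_minus_020_is_18_percent(self):
        pc = percent_change(-0.20, -0.39, -0.01)
        assert round(pc.percent) == 18

    def test_ci_bounds_swap_to_1_32(self):
        pc = percent_change(-0.20, -0.39, -0.01)
        assert pc.rounded == (18, 1, 32)

    def test_zero_beta_is_zero_percent(self):
        assert percent_change(0.0, -0.1, 0.1).percent == 0.0

    def test_monotone_in_beta(self):
        betas = np.linspace(-1.0, 1.0, 21)
        pcts = [percent_change(b, b - 0.1, b + 0.1).percent for b in betas]
        assert all(a > b for a, b in zip(pcts, pcts[1:]))

    def test_ci_nesting_preserved(self):
        wide = percent_change(-0.2, -0.5, 0.1)
        narrow = percent_change(-0.2, -0.4, 0.0)
        assert wide.ci_low_pct <= narrow.ci_low_pct
        assert wide.ci_high_pct >= narrow.ci_high_pct

    def test_coef_to_percent_from_fit(self):
        rng = np.random.default_rng(71)
        x = rng.uniform(1, 10, 38)
        y = rng.normal(14 - 0.2 * x, 0.6)
        res = fit_loglinear(summaries_from_xy(x, y), ["median_decile"])
        pc = coef_to_percent(res, "median_decile")
        est = res.predictors["median_decile"]
        assert pc.percent == pytest.approx((1 - math.exp(est.coef)) * 100)
        assert pc.ci_low_pct == pytest.approx((1 - math.exp(est.ci_high)) * 100)
        with pytest.raises(ConfigurationError):
            coef_to_percent(res, "log_area")

    def test_inverted_ci_rejected(self):
        with pytest.raises(ValidationError):
            percent_change(-0.2, 0.3, -0.3)


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = [1.0, 2.0, 5.0, 9.0, 12.0]
        y = [math.exp(v) for v in x]
        assert spearman(x, y).rho == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        r = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert r.rho == pytest.approx(-1.0)
        assert r.n == 4

    def test_against_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(83)
        for _ in range(150):
            n = 12
            x = rng.integers(1, 6, n).astype(float)  # ties guaranteed
            y = rng.normal(size=n)
            assert spearman(x, y).rho == pytest.approx(
                rank_then_pearson_oracle(x, y), abs=1e-12
            )

    def test_p_value_t_approximation(self):
        rng = np.random.default_rng(89)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r = spearman(x, y)
        t = r.rho * math.sqrt((r.n - 2) / (1 - r.rho**2))
        assert r.p_value == pytest.approx(2 * stats.t.sf(abs(t), r.n - 2), rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValidationError):
            spearman([1, 2], [1, 2, 3])
        with pytest.raises(ValidationError):
            spearman([1, 2, 3], [1, 2, 3])

    def test_sign_agreement_with_ols_slope(self):
        # Both statistics must agree on the direction of a real monotone
        # association. (On pure noise the two can disagree arbitrarily
        # close to zero, so the check is conditioned on |rho| > 0.1.)
        rng = np.random.default_rng(97)
        for true_slope in (-0.3, -0.1, 0.0, 0.1, 0.3):
            for _ in range(10):
                x = rng.uniform(1, 10, 38)
                y = rng.normal(14 + true_slope * x, 0.8)
                ss = summaries_from_xy(x, y)
                rho = spearman(
                    [s.median_decile for s in ss], [s.total_population for s in ss]
                ).rho
                slope = (
                    fit_loglinear(ss, ["median_decile"]).predictors["median_decile"].coef
                )
                if abs(rho) > 0.1:
                    assert np.sign(rho) == np.sign(slope)
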