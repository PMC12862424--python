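"""Agreement statistics: ICC vs ANOVA/pingouin oracles, OLS vs normal
equations, effect size, noncentral-F power vs simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfccmorph import (classify_icc, cohens_f2, fit_multiple_regression,
                       icc_two_way, mean_sd, posthoc_power)
from tfccmorph.errors import CollinearityError, ZeroVarianceError


def icc21_anova_oracle(x):
    """Hand two-way ANOVA mean squares -> ICC(2,1), written independently."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * np.sum((x.mean(1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(0) - grand) ** 2) / (k - 1)
    mse = (np.sum((x - grand) ** 2)
           - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_vectors_are_excellent(self):
        res = icc_two_way(np.column_stack([[1.0, 2, 3, 4], [1.0, 2, 3, 4]]))
        assert res.estimate == pytest.approx(1.0)
        assert res.band == "excellent"

    def test_constant_offset_penalized_matches_anova_oracle(self):
        x = np.array([[1.0, 11], [2, 12], [3, 13]])
        res = icc_two_way(x)
        assert res.estimate == pytest.approx(icc21_anova_oracle(x), abs=1e-12)
        assert res.estimate < 0.1  # absolute agreement punishes the offset
        assert res.band == "poor"

    def test_matches_pingouin_on_random_tables(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(10, 3, size=(12, 2))
        x[:, 1] += rng.normal(0, 1, 12)
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": ["a", "b"] * 12,
            "ratings": x.ravel(),
        })
        ref = pingouin.intraclass_corr(long, "targets", "raters",
                                       "ratings").set_index("Type")
        assert icc_two_way(x).estimate == pytest.approx(
            ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert icc_two_way(x, consistency=True).estimate == pytest.approx(
            ref.loc["ICC(C,1)", "ICC"], abs=1e-9)

    def test_too_few_pairs_and_zero_variance(self):
        with pytest.raises(ValueError):
            icc_two_way(np.ones((2, 2)))
        with pytest.raises(ZeroVarianceError):
            icc_two_way(np.full((5, 2), 7.0))

    def test_dataframe_input_with_specimen_column(self):
        df = pd.DataFrame({"specimen": [0, 1, 2, 3],
                           "method_a": [1.0, 2, 3, 4],
                           "method_b": [1.1, 2.2, 2.9, 4.1]})
        res = icc_two_way(df)
        assert res.estimate == pytest.approx(
            icc21_anova_oracle(df[["method_a", "method_b"]]), abs=1e-12)


class TestClassifyICC:
    @pytest.mark.parametrize("value,band", [
        (0.97, "excellent"), (0.3, "poor"), (0.8, "good"),
        (0.5, "moderate"), (0.75, "moderate"), (0.9, "good"),
        (0.95, "excellent"), (0.49999, "poor"),
    ])
    def test_bands(self, value, band):
        assert classify_icc(value) == band

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=-1.0, max_value=1.5, allow_nan=False))
    def test_total_monotone_step_function(self, e):
        band = classify_icc(e)
        assert band in ("poor", "moderate", "good", "excellent")
        # monotone: a larger estimate never drops to a lower band
        order = ["poor", "moderate", "good", "excellent"]
        assert order.index(classify_icc(e + 0.05)) >= order.index(band)


class TestRegression:
    def _hand_dataset(self, rng):
        n, k = 12, 3
        X = pd.DataFrame(rng.normal(size=(n, k)),
                         columns=["sup_area", "head_area", "tfc_thickness"])
        y = (2.0 + 1.5 * X.sup_area - 0.7 * X.head_area
             + 0.2 * X.tfc_thickness + rng.normal(0, 0.5, n))
        return y.to_numpy(), X

    def test_matches_normal_equation_oracle(self, rng):
        y, X = self._hand_dataset(rng)
        res = fit_multiple_regression(y, X)
        A = np.column_stack([np.ones(len(y)), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)
        for j, col in enumerate(X.columns):
            assert res.raw_coefficients[col] == pytest.approx(beta[j + 1],
                                                              abs=1e-8)
        resid = y - A @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)
        assert res.adjusted_r_squared <= res.r_squared
        assert res.cohens_f2 == pytest.approx(r2 / (1 - r2), abs=1e-10)

    def test_response_equal_to_one_predictor(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        res = fit_multiple_regression(X["a"].to_numpy(), X)
        assert res.r_squared == pytest.approx(1.0)
        assert res.raw_coefficients["a"] == pytest.approx(1.0, abs=1e-8)
        assert res.raw_coefficients["b"] == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_predictors_have_unit_vifs(self):
        X = pd.DataFrame({
            "a": [1.0, 1, -1, -1],
            "b": [1.0, -1, 1, -1],
            "c": [1.0, -1, -1, 1],
        })
        # n=4, k=3 is too small; tile to n=8 keeping orthogonality
        X = pd.concat([X, X], ignore_index=True)
        y = np.arange(8.0)
        res = fit_multiple_regression(y, X)
        for v in res.vifs.values():
            assert v == pytest.approx(1.0, abs=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        a = rng.normal(size=10)
        X = pd.DataFrame({"a": a, "twice_a": 2 * a, "b": rng.normal(size=10)})
        with pytest.raises(CollinearityError) as err:
            fit_multiple_regression(rng.normal(size=10), X)
        assert "twice_a" in err.value.columns

    def test_qq_export_lengths(self, rng):
        y, X = self._hand_dataset(rng)
        res = fit_multiple_regression(y, X)
        qq = res.qq_table()
        assert len(qq) == len(y)
        assert qq.theoretical_quantile.is_monotonic_increasing


class TestCohensF2:
    @pytest.mark.parametrize("r2,expected", [(0.0, 0.0), (0.5, 1.0)])
    def test_values(self, r2, expected):
        assert cohens_f2(r2) == pytest.approx(expected)

    def test_observed_effect_size_rounds_to_two_point_six_two(self):
        assert round(cohens_f2(0.724), 2) == 2.62

    def test_domain(self):
        with pytest.raises(ValueError):
            cohens_f2(1.0)


class TestPosthocPower:
    def test_zero_effect_gives_alpha(self):
        assert posthoc_power(0.0, 20, 3, 0.05).power == pytest.approx(0.05)

    def test_matches_monte_carlo_oracle(self, rng):
        """Independent simulation of the noncentral F ratio."""
        from scipy import stats

        res = posthoc_power(2.62, 11, 6, 0.05)
        assert res.noncentrality == pytest.approx(2.62 * 11)
        k, df2, lam = 6, 4, res.noncentrality
        n_draw = 400_000
        num = stats.ncx2.rvs(k, lam, size=n_draw, random_state=rng) / k
        den = stats.chi2.rvs(df2, size=n_draw, random_state=rng) / df2
        mc = float((num / den > res.critical_f).mean())
        assert res.power == pytest.approx(mc, abs=0.01)

    def test_monotone_in_effect_sample_size_and_alpha(self):
        grid_f2 = [posthoc_power(f2, 11, 6, 0.05).power
                   for f2 in (0.5, 1.0, 2.0, 4.0)]
        grid_n = [posthoc_power(2.62, n, 6, 0.05).power
                  for n in (11, 15, 20, 30)]
        grid_a = [posthoc_power(2.62, 11, 6, a).power
                  for a in (0.01, 0.05, 0.10)]
        for grid in (grid_f2, grid_n, grid_a):
            assert all(x < y for x, y in zip(grid, grid[1:]))

    def test_degrees_of_freedom_validation(self):
        with pytest.raises(ValueError):
            posthoc_power(1.0, 7, 6, 0.05)  # n - k - 1 = 0


class TestMeanSD:
    def test_values(self):
        assert mean_sd([1.0, 1, 1]) == (1.0, 0.0)
        assert mean_sd([1.0, 2, 3]) == (2.0, 1.0)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
    def test_shift_invariance_of_sd(self, shift):
        base = np.array([1.0, 2.5, 4.0, 8.0])
        m0, s0 = mean_sd(base)
        m1, s1 = mean_sd(base + shift)
        assert m1 == pytest.approx(m0 + shift, abs=1e-6)
        assert s1 == pytest.approx(s0, abs=1e-6)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            mean_sd([1.0])
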