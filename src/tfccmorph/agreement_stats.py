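"""Agreement and power statistics for paired anatomical measurements.

* Intraclass correlation, ICC(2,1): two-way random effects, absolute
  agreement, single measurement, computed from the two-way ANOVA mean
  squares.  Agreement bands follow the conventional thresholds:
  poor < 0.5 <= moderate <= 0.75 < good <= 0.9 < excellent.
* Multiple linear regression via OLS with standardized betas, variance
  inflation factors, Cohen's f² = R²/(1−R²), and residual/Q-Q exports.
* Post hoc power of the overall regression F test via the noncentral F
  distribution with noncentrality λ = f²·n (the fixed-model "R² deviation
  from zero" convention used by the G*Power tool).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, ZeroVarianceError

ICC_BANDS = ("poor", "moderate", "good", "excellent")


def classify_icc(estimate: float) -> str:
    """Agreement band of an ICC estimate.

    Boundaries: 0.5 and 0.75 belong to "moderate", 0.9 to "good".
    """
    e = float(estimate)
    if not np.isfinite(e):
        raise ValueError("ICC estimate must be finite")
    if e < 0.5:
        return "poor"
    if e <= 0.75:
        return "moderate"
    if e <= 0.9:
        return "good"
    return "excellent"


@dataclass
class ICCResult:
    estimate: float
    model_tag: str
    band: str
    n_pairs: int

    def to_json_dict(self) -> dict:
        return dict(self.__dict__)


def _as_pair_array(pairs) -> np.ndarray:
    if isinstance(pairs, pd.DataFrame):
        num = pairs.select_dtypes(include=[np.number])
        drop = [c for c in num.columns if c.lower() in ("specimen", "id")]
        num = num.drop(columns=drop)
        arr = num.to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) table of paired measurements")
    return arr


def icc_two_way(pairs, consistency: bool = False) -> ICCResult:
    """ICC of an (n, 2) paired-measurement table from two-way ANOVA.

    The default is ICC(2,1) — two-way random effects, absolute agreement,
    single measurement — the standard model for method comparison.
    ``consistency=True`` selects ICC(3,1) (two-way mixed, consistency),
    which ignores systematic offsets between the methods.
    """
    x = _as_pair_array(pairs)
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 complete pairs")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ZeroVarianceError("ICC undefined: zero total variance")
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if consistency:
        est = (msr - mse) / (msr + (k - 1) * mse)
        tag = "ICC(3,1) two-way mixed, consistency, single measurement"
    else:
        est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        tag = "ICC(2,1) two-way random, absolute agreement, single measurement"
    est = float(est)
    return ICCResult(est, tag, classify_icc(est), n)


# ---------------------------------------------------------------------------
# regression

@dataclass
class RegressionResult:
    raw_coefficients: dict[str, float]
    standardized_betas: dict[str, float]
    r_squared: float
    adjusted_r_squared: float
    f_statistic: float
    model_p_value: float
    p_values: dict[str, float]
    vifs: dict[str, float]
    cohens_f2: float
    n: int
    k: int
    intercept: float
    residuals: np.ndarray = field(repr=False, default=None)
    theoretical_quantiles: np.ndarray = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        d = {kk: v for kk, v in self.__dict__.items()
             if kk not in ("residuals", "theoretical_quantiles")}
        return d

    def qq_table(self) -> pd.DataFrame:
        """Sorted standardized residuals vs normal theoretical quantiles."""
        return pd.DataFrame({
            "theoretical_quantile": self.theoretical_quantiles,
            "standardized_residual": np.sort(self.residuals)
            / (np.std(self.residuals, ddof=1) or 1.0),
        })


def cohens_f2(r_squared: float) -> float:
    """Effect size f² = R² / (1 − R²)."""
    r2 = float(r_squared)
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r_squared must lie in [0, 1)")
    return r2 / (1.0 - r2)


def fit_multiple_regression(response, predictors: pd.DataFrame
                            ) -> RegressionResult:
    """OLS fit with diagnostics: R², adjusted R², F, VIF, β, f², Q-Q data."""
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(response, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k+1 observations (n={n}, k={k})")
    centered = X.to_numpy() - X.to_numpy().mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < k:
        # name (near-)dependent columns via auxiliary regressions
        bad = []
        for j, col in enumerate(X.columns):
            others = np.delete(centered, j, axis=1)
            xj = centered[:, j]
            if np.allclose(xj, 0):
                bad.append(col)
                continue
            coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
            resid = xj - others @ coef
            if np.sum(resid ** 2) <= 1e-10 * np.sum(xj ** 2):
                bad.append(col)
        raise CollinearityError(bad or list(X.columns))

    exog = sm.add_constant(X)
    fit = sm.OLS(y, exog).fit()

    zX = (X - X.mean()) / X.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    zfit = sm.OLS(zy, sm.add_constant(zX)).fit()

    vifs = {col: float(variance_inflation_factor(exog.to_numpy(), j + 1))
            for j, col in enumerate(X.columns)}

    resid = np.asarray(fit.resid)
    order = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theo = stats.norm.ppf(order)

    r2 = float(fit.rsquared)
    return RegressionResult(
        raw_coefficients={c: float(fit.params[c]) for c in X.columns},
        standardized_betas={c: float(zfit.params[c]) for c in X.columns},
        r_squared=r2,
        adjusted_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        model_p_value=float(fit.f_pvalue),
        p_values={c: float(fit.pvalues[c]) for c in X.columns},
        vifs=vifs,
        cohens_f2=cohens_f2(r2) if r2 < 1.0 else float("inf"),
        n=n, k=k,
        intercept=float(fit.params["const"]),
        residuals=resid,
        theoretical_quantiles=theo,
    )


# ---------------------------------------------------------------------------
# power

@dataclass
class PowerResult:
    power: float
    alpha: float
    f2: float
    n: int
    k: int
    noncentrality: float
    critical_f: float

    def to_json_dict(self) -> dict:
        return dict(self.__dict__)


def posthoc_power(f2: float, n: int, k: int, alpha: float) -> PowerResult:
    """Post hoc power of the overall F test of a fixed-effects regression.

    Noncentrality λ = f²·n; the critical value is the upper-α quantile of
    the central F(k, n−k−1); power is the upper tail of the noncentral
    F(k, n−k−1, λ) beyond it.  At f² = 0 the power equals α.
    """
    if f2 < 0:
        raise ValueError("f2 must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df2 = n - k - 1
    if k < 1 or df2 < 1:
        raise ValueError(f"invalid degrees of freedom (k={k}, n-k-1={df2})")
    lam = f2 * n
    crit = float(stats.f.isf(alpha, k, df2))
    if lam == 0:
        power = float(alpha)
    else:
        power = float(stats.ncf.sf(crit, k, df2, lam))
    return PowerResult(power, float(alpha), float(f2), int(n), int(k),
                       float(lam), crit)


def mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n−1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("mean_sd needs at least 2 values")
    return float(v.mean()), float(v.std(ddof=1))
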