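"""Statistical comparison of two structural-complexity indices.

Two indices measured on the same plots are compared with (a) Pearson's
correlation for goodness of fit and (b) Deming errors-in-variables
regression for a symmetric translation formula between the index scales.
Deming regression needs the ratio of the measurement-error standard
deviations of the two variables; lacking repeated measurements, that ratio
is taken to be the ratio of the observed index ranges (equal
signal-to-noise assumption). Standard errors and confidence intervals come
from a leave-one-out jackknife.

A third tool fits zero-intercept power laws t = a * N**b to per-plot
runtimes versus cloud size, to characterise how each index's cost scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DegenerateDataError, FitError

__all__ = [
    "DemingFit",
    "ScalingFit",
    "DemingRegression",
    "PowerLawScaling",
    "pearson",
    "error_ratio",
    "deming_regression",
    "per_group_deming",
    "fit_power_scaling",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DemingFit:
    """Symmetric regression line with jackknife uncertainty."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci_slope: tuple
    ci_intercept: tuple
    delta: float
    n: int


@dataclass(frozen=True)
class ScalingFit:
    """Zero-intercept power-law fit t = a * N**b."""

    a: float
    b: float
    se_a: float
    se_b: float
    r_squared: float


def pearson(x, y):
    """Sample Pearson correlation with the two-sided t-transform p-value.

    Returns ``(r, p)``; raises :class:`DegenerateDataError` when either
    variable has zero variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1D arrays of length >= 3")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise DegenerateDataError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def error_ratio(db_values, ce_values) -> float:
    """Range ratio range(Db)/range(CE), the assumed error-SD ratio delta.

    Both indices are assumed to carry measurement error proportional to
    their observed range (equal signal-to-noise), so the error-SD ratio
    sigma_Db/sigma_CE equals the range ratio.
    """
    db = np.asarray(db_values, dtype=np.float64)
    ce = np.asarray(ce_values, dtype=np.float64)
    db_range = float(db.max() - db.min())
    ce_range = float(ce.max() - ce.min())
    if db_range == 0.0 or ce_range == 0.0:
        raise DegenerateDataError("range ratio undefined for zero-range input")
    return db_range / ce_range


def _deming_slope_intercept(x, y, delta):
    """Closed-form Deming line for error-SD ratio delta = sigma_x/sigma_y.

    Internally the error-variance ratio lambda = sigma_y**2/sigma_x**2
    = 1/delta**2 enters the standard maximum-likelihood slope
    [syy - lam*sxx + sqrt((syy - lam*sxx)**2 + 4*lam*sxy**2)] / (2*sxy).
    """
    lam = 1.0 / (delta * delta)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).mean())
    syy = float(((y - ym) ** 2).mean())
    sxy = float(((x - xm) * (y - ym)).mean())
    if sxy == 0.0:
        raise DegenerateDataError("Deming slope undefined: zero covariance")
    d = syy - lam * sxx
    slope = (d + np.sqrt(d * d + 4 * lam * sxy * sxy)) / (2 * sxy)
    return slope, ym - slope * xm


class DemingRegression(RegressorMixin, BaseEstimator):
    """Errors-in-variables (Deming) regression with jackknife intervals.

    Parameters
    ----------
    delta : float, default 1.0
        Ratio of measurement-error standard deviations sigma_x/sigma_y.
        ``delta=1`` gives orthogonal (total least squares) regression.
    ci_level : float, default 0.95
        Confidence level of the jackknife intervals (t quantile, n-2 df).

    Attributes
    ----------
    slope_, intercept_ : float
    se_slope_, se_intercept_ : float
        Leave-one-out jackknife standard errors.
    ci_slope_, ci_intercept_ : tuple of (low, high)
    n_ : int

    Notes
    -----
    The fit is symmetric: swapping x and y while inverting ``delta``
    inverts the line rather than producing a different one, unlike
    ordinary least squares.
    """

    def __init__(self, delta: float = 1.0, ci_level: float = 0.95):
        self.delta = delta
        self.ci_level = ci_level

    def fit(self, X, y):
        x = np.asarray(X, dtype=np.float64).reshape(-1)
        y = np.asarray(y, dtype=np.float64).reshape(-1)
        if x.shape != y.shape or len(x) < 3:
            raise ValueError("need equal-length x and y with at least 3 points")
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        n = len(x)
        slope, intercept = _deming_slope_intercept(x, y, self.delta)

        loo_slopes = np.empty(n)
        loo_intercepts = np.empty(n)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            s_i, b_i = _deming_slope_intercept(x[mask], y[mask], self.delta)
            loo_slopes[i], loo_intercepts[i] = s_i, b_i
            mask[i] = True
        se_slope = float(np.sqrt((n - 1) / n * ((loo_slopes - loo_slopes.mean()) ** 2).sum()))
        se_intercept = float(
            np.sqrt((n - 1) / n * ((loo_intercepts - loo_intercepts.mean()) ** 2).sum())
        )
        t_crit = stats.t.ppf(0.5 + self.ci_level / 2, df=n - 2)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.se_slope_ = se_slope
        self.se_intercept_ = se_intercept
        self.ci_slope_ = (slope - t_crit * se_slope, slope + t_crit * se_slope)
        self.ci_intercept_ = (
            intercept - t_crit * se_intercept,
            intercept + t_crit * se_intercept,
        )
        self.n_ = n
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=np.float64).reshape(-1)
        return self.slope_ * x + self.intercept_

    def fit_result(self, X, y) -> DemingFit:
        self.fit(X, y)
        return DemingFit(
            slope=self.slope_,
            intercept=self.intercept_,
            se_slope=self.se_slope_,
            se_intercept=self.se_intercept_,
            ci_slope=self.ci_slope_,
            ci_intercept=self.ci_intercept_,
            delta=self.delta,
            n=self.n_,
        )


def deming_regression(x, y, delta: float) -> DemingFit:
    """Deming fit of y on x with error-SD ratio delta = sigma_x/sigma_y."""
    return DemingRegression(delta=delta).fit_result(x, y)


def per_group_deming(table: pd.DataFrame, delta_policy: str = "global") -> dict:
    """Deming fits per site label.

    Parameters
    ----------
    table : DataFrame with columns ``site``, ``db``, ``ce``.
    delta_policy : {"global", "per-group"}
        Whether the error ratio is computed once from the pooled data
        (default — a single printed delta applies to every site) or
        recomputed within each site.

    Returns
    -------
    dict mapping site label -> DemingFit. Sites with fewer than 3 rows
    are skipped with a logged warning.
    """
    if delta_policy not in ("global", "per-group"):
        raise ValueError(f"unknown delta_policy {delta_policy!r}")
    global_delta = error_ratio(table["db"], table["ce"])
    fits = {}
    for site, grp in table.groupby("site", sort=True):
        if len(grp) < 3:
            logger.warning(
                "site %r has only %d rows; skipping Deming fit", site, len(grp)
            )
            continue
        delta = (
            global_delta
            if delta_policy == "global"
            else error_ratio(grp["db"], grp["ce"])
        )
        fits[site] = deming_regression(grp["db"].to_numpy(), grp["ce"].to_numpy(), delta)
    return fits


class PowerLawScaling(RegressorMixin, BaseEstimator):
    """Zero-intercept power-law fit t = a * N**b by nonlinear least squares.

    Initialized from the log-log OLS line; parameter standard errors come
    from the Gauss-Newton covariance, and R**2 is reported on the original
    (untransformed) scale.

    Attributes
    ----------
    a_, b_ : float
    se_a_, se_b_ : float
    r_squared_ : float
    """

    def fit(self, X, y):
        n = np.asarray(X, dtype=np.float64).reshape(-1)
        t = np.asarray(y, dtype=np.float64).reshape(-1)
        if n.shape != t.shape or len(n) < 3:
            raise ValueError("need equal-length N and t with at least 3 points")
        if (n <= 0).any() or (t <= 0).any():
            raise ValueError("all N and t must be strictly positive")
        # log-log OLS start values
        ln_n, ln_t = np.log(n), np.log(t)
        b0 = float(np.polyfit(ln_n, ln_t, 1)[0])
        a0 = float(np.exp(ln_t.mean() - b0 * ln_n.mean()))
        fallback = ScalingFit(a0, b0, float("nan"), float("nan"), float("nan"))
        try:
            popt, pcov = optimize.curve_fit(
                lambda nn, a, b: a * nn ** b, n, t, p0=[a0, b0], maxfev=10000
            )
        except RuntimeError as exc:
            raise FitError(f"power-law fit did not converge: {exc}", fallback=fallback)
        a, b = popt
        se_a, se_b = np.sqrt(np.diag(pcov))
        resid = t - a * n ** b
        ss_tot = float(((t - t.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
        self.a_, self.b_ = float(a), float(b)
        self.se_a_, self.se_b_ = float(se_a), float(se_b)
        self.r_squared_ = r2
        return self

    def predict(self, X):
        n = np.asarray(X, dtype=np.float64).reshape(-1)
        return self.a_ * n ** self.b_

    def fit_result(self, X, y) -> ScalingFit:
        self.fit(X, y)
        return ScalingFit(self.a_, self.b_, self.se_a_, self.se_b_, self.r_squared_)


def fit_power_scaling(t, n) -> ScalingFit:
    """Fit runtime t (seconds) against cloud size n as t = a * N**b."""
    return PowerLawScaling().fit_result(n, t)
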