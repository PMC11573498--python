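"""Variance partitioning: how much of hinge size is controlled by age
(harvesting pressure channel) versus growth rate (environmental channel).

Per site, hinge size is regressed on biological age and the growth residual
from the global standardized curve, and each predictor receives a share of
the regression's explained variance via Johnson's relative weights: the
predictor matrix is replaced by its closest orthogonal counterpart (through
the singular value decomposition of the predictor correlation matrix), the
response is regressed on those orthogonal variables, and the squared
loadings map the variance shares back to the original, correlated
predictors.  Unnormalized weights sum to R-squared; normalized weights are
reported as percentages summing to 100.  A brute-force LMG decomposition
(incremental R-squared averaged over predictor orderings) serves as an
independent cross-check in the test suite, and variance inflation factors
diagnose multicollinearity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import Assemblage

logger = logging.getLogger(__name__)


@dataclass
class RegressionSummary:
    """OLS fit of a response on named predictors, with standardized slopes."""

    coef: dict[str, float]            # raw slopes (no intercept entry)
    coef_standardized: dict[str, float]
    intercept: float
    r_squared: float
    n: int
    p_overall: float


def _check_matrix(y: np.ndarray, x: np.ndarray) -> None:
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} observations, have {n}")
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("constant predictor")


def fit_regression(response, predictors: dict | pd.DataFrame) -> RegressionSummary:
    """Multiple OLS regression with intercept and standardized coefficients.

    Standardized slopes are the raw slopes of the same model fitted on
    z-scored response and predictors, so they are invariant to linear
    rescaling of any variable.
    """
    x_df = pd.DataFrame(predictors)
    y = np.asarray(response, dtype=float)
    x = x_df.to_numpy(float)
    _check_matrix(y, x)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    z = lambda v: (v - v.mean(axis=0)) / v.std(axis=0, ddof=1)
    fit_z = sm.OLS(z(y), sm.add_constant(z(x))).fit()
    names = list(x_df.columns)
    return RegressionSummary(
        coef=dict(zip(names, fit.params[1:])),
        coef_standardized=dict(zip(names, fit_z.params[1:])),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        n=y.size,
        p_overall=float(fit.f_pvalue),
    )


@dataclass
class RelativeWeights:
    """Shares of explained variance per predictor."""

    names: list[str]
    raw: np.ndarray      # sums to r_squared
    pct: np.ndarray      # sums to 100
    r_squared: float
    n: int


def relative_weights(response, predictors: dict | pd.DataFrame) -> RelativeWeights:
    """Johnson's relative weights for two or more correlated predictors."""
    x_df = pd.DataFrame(predictors)
    y = np.asarray(response, dtype=float)
    x = x_df.to_numpy(float)
    _check_matrix(y, x)
    xz = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    n = y.size
    rxx = (xz.T @ xz) / (n - 1)
    evals, evecs = np.linalg.eigh(rxx)
    if evals.min() < 1e-10:
        raise ValueError("predictor matrix is (near-)rank-deficient")
    lam = evecs @ np.diag(np.sqrt(evals)) @ evecs.T   # Rxx^(1/2)
    rxy = (xz.T @ yz) / (n - 1)
    beta = np.linalg.solve(lam, rxy)                  # loadings on orthogonal vars
    raw = (lam**2) @ (beta**2)
    r2 = float(rxy @ np.linalg.solve(rxx, rxy))
    pct = 100.0 * raw / raw.sum()
    return RelativeWeights(
        names=list(x_df.columns), raw=raw, pct=pct, r_squared=r2, n=n
    )


def lmg_weights(response, predictors: dict | pd.DataFrame) -> np.ndarray:
    """Brute-force LMG importance: incremental R-squared of each predictor
    averaged over all orders of entry.  Exponential in the number of
    predictors; meant as a small-p oracle, not a production path."""
    x_df = pd.DataFrame(predictors)
    y = np.asarray(response, dtype=float)
    names = list(x_df.columns)
    p = len(names)

    def r2_of(subset: tuple) -> float:
        if not subset:
            return 0.0
        x = x_df[list(subset)].to_numpy(float)
        return float(sm.OLS(y, sm.add_constant(x)).fit().rsquared)

    totals = np.zeros(p)
    orders = list(permutations(range(p)))
    for order in orders:
        seen: tuple = ()
        for j in order:
            before = r2_of(tuple(names[i] for i in seen))
            seen = seen + (j,)
            after = r2_of(tuple(names[i] for i in seen))
            totals[j] += after - before
    return totals / len(orders)


def compute_vif(predictors: dict | pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1/(1 - R2_j).

    Computed as the diagonal of the inverse predictor correlation matrix;
    perfect collinearity yields +inf for every predictor.
    """
    x_df = pd.DataFrame(predictors)
    x = x_df.to_numpy(float)
    if x.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("constant predictor")
    xz = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    rxx = (xz.T @ xz) / (x.shape[0] - 1)
    try:
        inv = np.linalg.inv(rxx)
        vif = np.diag(inv).copy()
        if np.linalg.cond(rxx) > 1e12:
            vif[:] = np.inf
    except np.linalg.LinAlgError:
        vif = np.full(x.shape[1], np.inf)
    return pd.Series(vif, index=x_df.columns, name="vif")


def _site_table(df: pd.DataFrame, min_n: int, min_levels: int) -> dict | None:
    n = len(df)
    if n < 5:
        return None
    age = df["age_years"].to_numpy(float)
    resid = df["residual_mm"].to_numpy(float)
    hinge = df["hinge_mm"].to_numpy(float)
    if np.ptp(age) == 0 or np.ptp(resid) == 0 or np.ptp(hinge) == 0:
        return None
    rw = relative_weights(hinge, {"age": age, "growth": resid})
    n_levels = int(df["layer_order"].dropna().nunique())
    return {
        "n": n,
        "n_levels": n_levels,
        "r_squared": rw.r_squared,
        "weight_age_pct": float(rw.pct[0]),
        "weight_growth_pct": float(rw.pct[1]),
        "reliable": bool(n >= min_n and n_levels >= min_levels),
    }


def partition_by_site(
    assemblage: Assemblage,
    residuals: pd.DataFrame,
    min_n: int = 30,
    min_levels: int = 4,
) -> pd.DataFrame:
    """Relative-weights partition of hinge size per site.

    One row per site with enough complete records (hinge + age + residual
    from the global curve).  Sites below ``min_n`` complete records or with
    fewer than ``min_levels`` distinct stratigraphic levels are flagged
    ``reliable=False`` — short sequences give weak, unstable attributions
    and are excluded from headline tables.
    """
    df = assemblage.complete().merge(residuals, on="shell_id", how="inner")
    rows = []
    for site, grp in df.groupby("site", sort=True):
        entry = _site_table(grp, min_n, min_levels)
        if entry is None:
            logger.info("site %s skipped: too few usable records (n=%d)", site, len(grp))
            continue
        rows.append({"site": site, **entry})
    cols = ["site", "n", "n_levels", "r_squared",
            "weight_age_pct", "weight_growth_pct", "reliable"]
    return pd.DataFrame(rows, columns=cols)


def partition_pooled(assemblage: Assemblage, residuals: pd.DataFrame) -> RelativeWeights:
    """Relative weights over all complete records pooled across sites."""
    df = assemblage.complete().merge(residuals, on="shell_id", how="inner")
    return relative_weights(
        df["hinge_mm"].to_numpy(float),
        {
            "age": df["age_years"].to_numpy(float),
            "growth": df["residual_mm"].to_numpy(float),
        },
    )
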