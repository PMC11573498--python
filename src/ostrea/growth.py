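"""Standardized growth curve: von Bertalanffy fitting and residuals.

Hinge size at age is modelled with the von Bertalanffy growth function

    H_s(A) = H_inf * (1 - exp(-k * (A - t0)))

where ``H_inf`` is the asymptotic hinge size (mm), ``k`` the growth-rate
coefficient (1/yr) and ``t0`` the hypothetical age of zero hinge size (yr).
One global curve is fitted by nonlinear least squares over all shells with
both hinge and age, pooled across sites and periods; it is the *standard*
against which each shell's growing conditions are judged.  A shell's growth
residual

    r_i = H_i - H_s(A_i)

is its observed hinge minus the standard hinge at its age: negative means
it grew slower than a typical shell of that age (poor conditions), positive
faster.  The fit is deterministic: starting values follow a fixed rule and
the optimizer uses no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import linregress

from .data import Assemblage


class GrowthFitError(ValueError):
    """Base class for growth-curve fitting failures."""


class InsufficientDataError(GrowthFitError):
    """Fewer complete records or distinct ages than the model needs."""


class DegenerateFitError(GrowthFitError):
    """Data cannot identify the curve (e.g. zero hinge variation)."""


@dataclass(frozen=True)
class GrowthCurveParams:
    """The three von Bertalanffy parameters."""

    h_inf: float  # asymptotic hinge size, mm
    k: float      # growth-rate coefficient, 1/yr
    t0: float     # hypothetical age at zero hinge size, yr

    def __post_init__(self) -> None:
        if not (self.h_inf > 0 and self.k > 0):
            raise ValueError("h_inf and k must be positive")


@dataclass(frozen=True)
class GrowthFitResult:
    params: GrowthCurveParams
    ssr: float          # sum of squared residuals, mm^2
    n_used: int         # complete records entering the fit
    converged: bool
    iterations: int     # objective evaluations used by the optimizer
    message: str = ""


def predict_hinge(params: GrowthCurveParams, age):
    """Standard hinge size (mm) at ``age`` (scalar or array of years)."""
    a = np.asarray(age, dtype=float)
    out = params.h_inf * (1.0 - np.exp(-params.k * (a - params.t0)))
    return float(out) if np.isscalar(age) or a.ndim == 0 else out


def _initial_guess(hinge: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Deterministic starting values.

    H_inf starts 5% above the largest observed hinge; k comes from the slope
    of the log-linearized curve, log(1 - H/H_inf0) = -k*(A - t0); t0 starts
    at 0 (clipped below the youngest age).
    """
    h_inf0 = 1.05 * float(hinge.max())
    y = np.log(1.0 - hinge / h_inf0)
    k0 = 0.2
    if np.unique(age).size >= 2:
        slope = linregress(age, y).slope
        if slope < 0:
            k0 = -slope
    t00 = min(0.0, float(age.min()) - 0.5)
    return np.array([h_inf0, max(k0, 1e-3), t00])


def fit_growth_curve(
    assemblage: Assemblage,
    xtol: float = 1e-8,
    max_nfev: int = 500,
) -> GrowthFitResult:
    """Fit the global standardized growth curve by least squares.

    Uses every record with both hinge and age.  Requires at least 4 complete
    records and 3 distinct ages.  Parameters are bounded away from
    degenerate sign flips (h_inf in (0, 10*max hinge], k in (0, 10],
    t0 in [-10, min age)); a fit pinned at k ~ 0 is reported as degenerate.
    """
    complete = assemblage.complete()
    hinge = complete["hinge_mm"].to_numpy(float)
    age = complete["age_years"].to_numpy(float)
    n = hinge.size
    if n < 4:
        raise InsufficientDataError(
            f"need >= 4 records with both hinge and age, have {n}"
        )
    if np.unique(age).size < 3:
        raise InsufficientDataError("need >= 3 distinct ages")
    if np.ptp(hinge) == 0:
        raise DegenerateFitError(
            "all hinges equal: growth-rate coefficient k is not identifiable"
        )

    def resid(x):
        h_inf, k, t0 = x
        return hinge - h_inf * (1.0 - np.exp(-k * (age - t0)))

    def jac(x):
        h_inf, k, t0 = x
        e = np.exp(-k * (age - t0))
        return np.column_stack([-(1.0 - e), -h_inf * (age - t0) * e, h_inf * k * e])

    lower = np.array([1e-6, 1e-6, -10.0])
    upper = np.array([10.0 * hinge.max(), 10.0, float(age.min()) - 1e-6])
    x0 = np.clip(_initial_guess(hinge, age), lower, upper)
    sol = least_squares(
        resid, x0, jac=jac, bounds=(lower, upper),
        xtol=xtol, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
    )
    h_inf, k, t0 = (float(v) for v in sol.x)
    if k <= 1e-6:
        raise DegenerateFitError(f"fitted k = {k:.2e} is effectively zero")
    return GrowthFitResult(
        params=GrowthCurveParams(h_inf=h_inf, k=k, t0=t0),
        ssr=float(np.sum(sol.fun**2)),
        n_used=n,
        converged=bool(sol.status > 0),
        iterations=int(sol.nfev),
        message=str(sol.message),
    )


def fit_growth_curves_by_site(assemblage: Assemblage, **kwargs) -> dict[str, GrowthFitResult]:
    """Optional per-site curves (the default analysis uses one global curve)."""
    out: dict[str, GrowthFitResult] = {}
    for site, grp in assemblage.records.groupby("site", sort=True):
        try:
            out[site] = fit_growth_curve(
                Assemblage(grp, provenance=f"{assemblage.provenance}[{site}]"), **kwargs
            )
        except GrowthFitError:
            continue
    return out


def compute_residuals(params: GrowthCurveParams, assemblage: Assemblage) -> pd.DataFrame:
    """Per-shell growth residuals r_i = H_i - H_s(A_i).

    Returns a frame ``shell_id, residual_mm`` with one row per record having
    both hinge and age; join on ``shell_id`` to recover site/period/layer.
    """
    complete = assemblage.complete()
    pred = predict_hinge(params, complete["age_years"].to_numpy(float))
    return pd.DataFrame(
        {
            "shell_id": complete["shell_id"].to_numpy(),
            "residual_mm": complete["hinge_mm"].to_numpy(float) - pred,
        }
    )
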