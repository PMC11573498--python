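"""Two-group statistical comparisons between cultural periods.

Location differences (hinge, derived length, age, growth residual) between
the Mesolithic and Neolithic are tested with two-sided Mann–Whitney U tests;
spread differences in hinge size with the variance-ratio F test and Levene's
test.  Site-level period comparisons form a Bonferroni family per variable
(one family = the per-site tests of one variable, matching how the results
are reported site by site).

Mann–Whitney: ages are small integers, so ties are pervasive — mid-ranks
with the tie-corrected normal approximation are used for groups of 8 or
more; below that the exact null distribution is enumerated over all
assignments of the pooled mid-ranks, which stays correct under ties (a case
library exact methods typically refuse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conversion import hinge_to_length
from .data import PERIOD_MESOLITHIC, PERIOD_NEOLITHIC, Assemblage

logger = logging.getLogger(__name__)

VARIABLES = ("hinge", "length", "age", "residual")

#: largest per-group size using exact Mann-Whitney enumeration
EXACT_MAX_N = 7


def significance_stars(p: float) -> int:
    """0-3 stars: p<0.05 -> 1, p<0.01 -> 2, p<0.001 -> 3."""
    return int(p < 0.05) + int(p < 0.01) + int(p < 0.001)


@dataclass
class ComparisonResult:
    """One two-group test outcome."""

    test: str                       # mann_whitney_u | variance_f | levene
    statistic: float
    p_raw: float
    variable: str | None = None
    group_a: str = "a"
    group_b: str = "b"
    n_a: int = 0
    n_b: int = 0
    p_adjusted: float | None = None

    @property
    def stars(self) -> int:
        p = self.p_raw if self.p_adjusted is None else self.p_adjusted
        return significance_stars(p)


def _as_samples(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return a, b


def _mw_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration with mid-ranks.

    p = P(|U - n_a n_b / 2| >= observed deviation) over all C(n, n_a)
    equally likely assignments of pooled ranks to group a.
    """
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    base = n_a * (n_a + 1) / 2.0
    u_obs = ranks[:n_a].sum() - base
    mu = n_a * n_b / 2.0
    dev = abs(u_obs - mu) - 1e-9
    hits = 0
    for idx in combinations(range(n_a + n_b), n_a):
        u = ranks[list(idx)].sum() - base
        if abs(u - mu) >= dev:
            hits += 1
    return float(u_obs), hits / comb(n_a + n_b, n_a)


def mann_whitney(sample_a, sample_b) -> ComparisonResult:
    """Two-sided Mann-Whitney U test (U reported for sample_a).

    Exact enumeration when both groups have fewer than 8 observations,
    tie-corrected continuity-corrected normal approximation otherwise.
    """
    a, b = _as_samples(sample_a, sample_b)
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N:
        u, p = _mw_exact(a, b)
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        u, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        test="mann_whitney_u", statistic=u, p_raw=min(p, 1.0),
        n_a=a.size, n_b=b.size,
    )


def variance_f_test(sample_a, sample_b) -> ComparisonResult:
    """Two-sided variance-ratio F test, larger variance in the numerator."""
    a, b = _as_samples(sample_a, sample_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2 for a variance test")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    if va >= vb:
        f, dfn, dfd = (np.inf if vb == 0 else va / vb), a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p = 0.0 if np.isinf(f) else min(1.0, 2.0 * stats.f.sf(f, dfn, dfd))
    return ComparisonResult(
        test="variance_f", statistic=float(f), p_raw=p, n_a=a.size, n_b=b.size
    )


def levene_test(sample_a, sample_b, center: str = "mean") -> ComparisonResult:
    """Levene's test for equal spread (classical mean-centered by default;
    ``center="median"`` gives the Brown-Forsythe variant)."""
    a, b = _as_samples(sample_a, sample_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2 for a spread test")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    stat, p = stats.levene(a, b, center=center)
    return ComparisonResult(
        test="levene", statistic=float(stat), p_raw=float(p), n_a=a.size, n_b=b.size
    )


def bonferroni_adjust(
    p_values: Sequence[float], family_size: int | None = None
) -> np.ndarray:
    """p_adj = min(1, m*p); m defaults to the number of p-values supplied."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < 1:
        raise ValueError("family_size must be >= 1")
    return np.minimum(1.0, m * p)


def _variable_values(df: pd.DataFrame, variable: str, coefficient: float) -> pd.Series:
    if variable == "hinge":
        return df["hinge_mm"].dropna().astype(float)
    if variable == "length":
        h = df["hinge_mm"].dropna().astype(float)
        return pd.Series(hinge_to_length(h.to_numpy(), coefficient), index=h.index)
    if variable == "age":
        return df["age_years"].dropna().astype(float)
    if variable == "residual":
        return df["residual_mm"].dropna().astype(float)
    raise ValueError(f"unknown variable {variable!r}; expected one of {VARIABLES}")


def compare_by_period(
    assemblage: Assemblage,
    residuals: pd.DataFrame | None = None,
    variables: Sequence[str] | None = None,
    sites: Sequence[str] | None = None,
    min_n: int = 2,
    levene_center: str = "mean",
    coefficient: float = 35.4,
) -> pd.DataFrame:
    """Mesolithic-vs-Neolithic comparisons, pooled and per site.

    Returns a long-format frame with columns ``variable, level, site, test,
    group_a, n_a, group_b, n_b, statistic, p_raw, p_adjusted, stars``.
    Pooled rows: Mann-Whitney per variable, plus F and Levene spread tests
    for hinge.  Site rows: Mann-Whitney at each site where both periods have
    at least ``min_n`` values of the variable; their p-values are Bonferroni
    adjusted as one family per variable.  Sites lacking a period are skipped
    with a logged diagnostic.
    """
    if variables is None:
        variables = ["hinge", "length", "age"] + (
            ["residual"] if residuals is not None else []
        )
    df = assemblage.records
    if residuals is not None:
        df = df.merge(residuals, on="shell_id", how="left")
    meso = df[df["period"] == PERIOD_MESOLITHIC]
    neo = df[df["period"] == PERIOD_NEOLITHIC]
    if meso.empty or neo.empty:
        raise ValueError("both periods must be present for period comparisons")

    rows: list[dict] = []

    def emit(res: ComparisonResult, variable: str, level: str, site: str) -> None:
        rows.append(
            {
                "variable": variable,
                "level": level,
                "site": site,
                "test": res.test,
                "group_a": PERIOD_MESOLITHIC,
                "n_a": res.n_a,
                "group_b": PERIOD_NEOLITHIC,
                "n_b": res.n_b,
                "statistic": res.statistic,
                "p_raw": res.p_raw,
                "p_adjusted": res.p_adjusted,
                "stars": res.stars,
            }
        )

    for variable in variables:
        a = _variable_values(meso, variable, coefficient).to_numpy()
        b = _variable_values(neo, variable, coefficient).to_numpy()
        if a.size >= min_n and b.size >= min_n:
            res = mann_whitney(a, b)
            res.p_adjusted = res.p_raw  # pooled test: family of one
            emit(res, variable, "pooled", "")
            if variable == "hinge":
                for spread in (variance_f_test(a, b), levene_test(a, b, levene_center)):
                    spread.p_adjusted = spread.p_raw
                    emit(spread, variable, "pooled", "")

    site_list = sorted(df["site"].unique()) if sites is None else list(sites)
    for variable in variables:
        site_rows: list[tuple[str, ComparisonResult]] = []
        for site in site_list:
            sub = df[df["site"] == site]
            a = _variable_values(
                sub[sub["period"] == PERIOD_MESOLITHIC], variable, coefficient
            ).to_numpy()
            b = _variable_values(
                sub[sub["period"] == PERIOD_NEOLITHIC], variable, coefficient
            ).to_numpy()
            if a.size < min_n or b.size < min_n:
                logger.info(
                    "site %s skipped for %s: periods have n=(%d, %d) < %d",
                    site, variable, a.size, b.size, min_n,
                )
                continue
            site_rows.append((site, mann_whitney(a, b)))
        if site_rows:
            adj = bonferroni_adjust([r.p_raw for _, r in site_rows])
            for (site, res), p_adj in zip(site_rows, adj):
                res.p_adjusted = float(p_adj)
                emit(res, variable, "site", site)

    return pd.DataFrame(
        rows,
        columns=[
            "variable", "level", "site", "test", "group_a", "n_a",
            "group_b", "n_b", "statistic", "p_raw", "p_adjusted", "stars",
        ],
    )
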