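"""Layer-by-layer sequences and simple trend descriptors per site.

Sites excavated by context (natural layers) or by arbitrary spits both end
up with an integer ``layer_order`` (larger = stratigraphically later); once
that rank exists the two conventions are treated identically.  A layer
sequence summarizes hinge, age, and growth residual per layer in
stratigraphic order; trend descriptors condense it into runs of
same-direction layer-to-layer change and the concordance between age and
size movements.

Step signs use a dead band (default 0.05 mm for hinge/residual, 0.1 yr for
age): one-decimal caliper precision makes smaller steps meaningless.
Within-band steps count as ties; ties break runs and count as
non-concordant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Assemblage

DEAD_BAND = {"hinge": 0.05, "residual": 0.05, "age": 0.1}

_VAR_COL = {"hinge": "hinge_mm", "age": "age_years", "residual": "residual_mm"}


def layer_sequence(
    assemblage: Assemblage,
    residuals: pd.DataFrame | None = None,
    site: str | None = None,
) -> pd.DataFrame:
    """Per-layer summaries for one site, sorted by ``layer_order``.

    Columns: site, layer_label, layer_order, period, n_hinge/n_age/
    n_residual, mean_* and sd_* per variable.  Requires at least two layers
    with a stratigraphic order.
    """
    df = assemblage.records
    if site is not None:
        df = df[df["site"] == site]
    if df.empty:
        raise ValueError(f"no records for site {site!r}")
    site_name = site if site is not None else df["site"].iloc[0]
    df = df[df["layer_order"].notna()].copy()
    if df["layer_order"].nunique() < 2:
        raise ValueError(f"site {site_name!r} has < 2 ordered stratigraphic layers")
    if residuals is not None:
        df = df.merge(residuals, on="shell_id", how="left")
    else:
        df["residual_mm"] = np.nan

    rows = []
    for order, grp in df.groupby("layer_order", sort=True):
        periods = grp["period"].mode()
        row: dict = {
            "site": site_name,
            "layer_label": grp["layer_label"].iloc[0],
            "layer_order": int(order),
            "period": periods.iloc[0] if len(periods) else "unassigned",
        }
        for var, col in _VAR_COL.items():
            vals = grp[col].dropna().to_numpy(float)
            row[f"n_{var}"] = vals.size
            row[f"mean_{var}"] = float(vals.mean()) if vals.size else np.nan
            row[f"sd_{var}"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).sort_values("layer_order").reset_index(drop=True)


@dataclass
class TrendDescriptor:
    """Runs of same-direction change along the stratigraphic sequence."""

    variable: str
    direction_runs: list[tuple[int, int]]  # (span in steps, sign in {-1,0,+1})
    concordance_age_size: float | None     # shared across variables


def _step_signs(means: np.ndarray, band: float) -> np.ndarray:
    d = np.diff(means)
    signs = np.sign(d)
    signs[np.abs(d) < band] = 0
    signs[np.isnan(d)] = 0
    return signs.astype(int)


def _runs(signs: np.ndarray) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    for s in (int(v) for v in signs):
        if runs and runs[-1][1] == s:
            runs[-1] = (runs[-1][0] + 1, s)
        else:
            runs.append((1, s))
    return runs


def trend_descriptors(
    sequence: pd.DataFrame, dead_band: dict[str, float] | None = None
) -> dict[str, TrendDescriptor]:
    """Trend descriptors per variable from a layer-sequence frame.

    A variable needs >= 3 layers with a mean to get a descriptor.
    ``concordance_age_size`` is the fraction of adjacent-layer steps where
    age and hinge move in the same (non-tied) direction; it is attached to
    every descriptor and is None when either variable lacks steps.
    """
    band = dict(DEAD_BAND)
    if dead_band:
        band.update(dead_band)
    seq = sequence.sort_values("layer_order")
    signs: dict[str, np.ndarray] = {}
    for var in _VAR_COL:
        means = seq[f"mean_{var}"].to_numpy(float)
        if np.sum(~np.isnan(means)) >= 3:
            signs[var] = _step_signs(means, band[var])
    if not signs:
        raise ValueError("need >= 3 layers with data for trend descriptors")

    concordance = None
    if "age" in signs and "hinge" in signs:
        sa, sh = signs["age"], signs["hinge"]
        # ties (sign 0) count as non-concordant
        concordance = float(np.mean((sa == sh) & (sa != 0)))

    return {
        var: TrendDescriptor(
            variable=var,
            direction_runs=_runs(s),
            concordance_age_size=concordance,
        )
        for var, s in signs.items()
    }
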