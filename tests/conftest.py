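import numpy as np
import pandas as pd
import pytest

from ostrea.data import CANONICAL_COLUMNS, Assemblage


def make_assemblage(
    hinges=None,
    ages=None,
    sites="A",
    periods="Mesolithic",
    layer_orders=None,
    provenance="test",
):
    """Build an assemblage from parallel value sequences (None = missing)."""
    n = next(
        len(s)
        for s in (hinges, ages)
        if s is not None and not np.isscalar(s)
    )

    def broadcast(v):
        return [v] * n if np.isscalar(v) or isinstance(v, str) or v is None else list(v)

    hinges = broadcast(hinges) if hinges is not None else [None] * n
    ages = broadcast(ages) if ages is not None else [None] * n
    sites_l = broadcast(sites)
    periods_l = broadcast(periods)
    orders = broadcast(layer_orders) if layer_orders is not None else [None] * n
    df = pd.DataFrame(
        {
            "shell_id": [f"sh{i:04d}" for i in range(n)],
            "site": sites_l,
            "period": periods_l,
            "layer_label": [None if o is None else f"L{o}" for o in orders],
            "layer_order": orders,
            "hinge_mm": [np.nan if h is None else float(h) for h in hinges],
            "age_years": [pd.NA if a is None else int(a) for a in ages],
        },
        columns=CANONICAL_COLUMNS,
    )
    return Assemblage(df, provenance=provenance)


@pytest.fixture
def simple_csv(tmp_path):
    path = tmp_path / "shells.csv"
    path.write_text(
        "shell_id,site,period,layer_label,layer_order,hinge_mm,age_years\n"
        "a1,SiteA,Mesolithic,L1,1,1.3,\n"
        "a2,SiteA,Mesolithic,L1,1,6.0,NA\n"
        "a3,SiteA,Neolithic,L2,2,33.4,\n"
    )
    return path
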