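#!/usr/bin/env python
"""Summary metrics and Mesolithic-vs-Neolithic comparisons per scenario.

Writes a six-number summary table (hinge, derived length, age) and the
long-format comparison table (Mann-Whitney location tests per variable,
F/Levene spread tests for hinge, pooled and per site with Bonferroni
adjustment) under results/comparisons/.
"""

from pathlib import Path

import pandas as pd

from ostrea.compare import compare_by_period
from ostrea.data import read_assemblage, summarize_metrics
from ostrea.simulate import PRESET_NAMES

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "comparisons"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in PRESET_NAMES:
        asm = read_assemblage(ROOT / "assemblages" / f"{name}.csv")
        resid = pd.read_csv(ROOT / "growth" / f"{name}_residuals.csv")
        summary = summarize_metrics(asm, rounded=True)
        summary.reset_index(names="variable").to_csv(
            OUT / f"{name}_summary.csv", index=False
        )
        comp = compare_by_period(asm, resid)
        comp.to_csv(OUT / f"{name}_period_tests.csv", index=False)
        pooled = comp[(comp["level"] == "pooled")
                      & (comp["test"] == "mann_whitney_u")]
        flags = ", ".join(
            f"{row.variable}: p_adj={row.p_adjusted:.3g}{'*' * int(row.stars)}"
            for row in pooled.itertuples()
        )
        print(f"{name:24s} pooled period tests -> {flags}")
    print(f"\nwrote summaries and comparison tables to {OUT}")


if __name__ == "__main__":
    main()
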