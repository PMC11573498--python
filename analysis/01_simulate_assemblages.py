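#!/usr/bin/env python
"""Generate the four study scenarios as synthetic assemblages.

Writes one canonical assemblage CSV plus a hidden-truth sidecar per
scenario under results/assemblages/.  The scenarios span the causal space
the pipeline must disentangle: a stationary null, a pure harvesting-
pressure shift, a pure environmental decline, and a mixed drift.
"""

from pathlib import Path

from ostrea.data import write_assemblage
from ostrea.simulate import PRESET_NAMES, preset, simulate_assemblage

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results" / "assemblages"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in PRESET_NAMES:
        assemblage, truth = simulate_assemblage(preset(name, seed=SEED))
        write_assemblage(assemblage, OUT / f"{name}.csv")
        truth.to_csv(OUT / f"{name}_truth.csv", index=False)
        print(
            f"{name:24s} n={assemblage.n_total:5d} "
            f"(both measured: {assemblage.n_both}, hinge only: "
            f"{assemblage.n_hinge_only}, age only: {assemblage.n_age_only})"
        )
    print(f"\nwrote assemblages to {OUT}")


if __name__ == "__main__":
    main()
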