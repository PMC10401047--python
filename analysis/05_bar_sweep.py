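#!/usr/bin/env python
"""Sensitivity of the MLR to the below/above-ground biomass ratio (BAR).

Recomputes each variant's minimum light requirement for BAR = 1..10,
holding every other parameter (including below-ground respiration per
unit biomass) fixed. Larger below-ground burdens raise the threshold;
without facilitation the non-acclimating plant's requirement escalates
sharply past BAR = 9.

Output: results/bar_sweep.csv
"""

from pathlib import Path

import pandas as pd

from seagrass_mlr import bar_sweep, default_parameters, make_scenario

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

VARIANTS = {
    "non-acclimation": (False, False),
    "acclimation": (True, False),
    "non-acclimation+facilitation": (False, True),
    "acclimation+facilitation": (True, True),
}


def main() -> None:
    params = default_parameters()
    rows = []
    for name, (acc, fac) in VARIANTS.items():
        for bar, res in bar_sweep(make_scenario(acc, fac, params=params), ref=params.light):
            rows.append(
                {
                    "scenario": name,
                    "bar": int(bar),
                    "mlr_percent_si": None if res is None else round(res.mlr_percent_si, 2),
                    "note": "no viable light level" if res is None else "",
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "bar_sweep.csv", index=False)

    def at(scn, bar):
        v = df[(df.scenario == scn) & (df.bar == bar)].mlr_percent_si.iloc[0]
        return "none" if pd.isna(v) else f"{v:.2f}% SI"

    print(f"BAR=9, no facilitation: acclimation {at('acclimation', 9)} vs "
          f"non-acclimation {at('non-acclimation', 9)}")
    print(f"BAR=10, facilitation+acclimation: {at('acclimation+facilitation', 10)}")
    print("-> heavy below-ground burdens sharply raise light requirements; "
          "acclimation buys several-fold headroom until thresholds approach full sun")


if __name__ == "__main__":
    main()
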