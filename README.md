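# seagrass-mlr

Carbon-balance models of seagrass persistence under light limitation,
built around the Mediterranean species *Cymodocea nodosa*. The package
asks two questions that matter for anyone managing meadows facing
coastal darkening: **how much light does a meadow need to persist**
(its minimum light requirement, MLR), and **does it collapse gradually
or abruptly** as light declines?

## The model

Total biomass density `B` (g DW m⁻²) follows a single ODE balancing
photosynthetic carbon gain against respiration and mortality:

```
dB/dt = K · 1/(1+BAR) · (½·P(I) − (R + RRR·BAR)) · B · (1 − B/N) − δ(B)
P(I)  = P_max · I / (I + I_k)
```

with irradiance `I` (µmol quanta m⁻² s⁻¹), conversion efficiency `K`,
below/above-ground biomass ratio `BAR`, below-ground respiration `RRR`,
carrying capacity `N`, and mortality `δ(B)`. The ½ reflects
photosynthesis running 12 h of 24 while respiration never stops. Two
switchable mechanisms give four model variants:

* **Photoacclimation** — `P_max`, `I_k` and `R` follow four-parameter
  logistic (sigmoid) functions of irradiance, mimicking how shaded
  leaves lower their respiration and saturation irradiance;
* **Self-facilitation** — per-capita mortality declines with biomass
  (clonal integration), `δ(B) = (1+e^{−λ_B B₀})/(1+e^{λ_B(B−B₀)}) · d₀B`,
  the ingredient that can produce bistability (vegetated and bare states
  coexisting, separated by an unstable equilibrium).

Because the ODE is one-dimensional, its full bifurcation structure is
recovered by root-finding: equilibria are zeros of `dB/dt` classified by
the slope's sign, the MLR is the lowest irradiance admitting a positive
stable state, and the bistable window runs from the fold (saddle-node)
bifurcation up to the transcritical point where the bare state
destabilizes. Resilience of the vegetated state is quantified as
`100·(B_stable − B_unstable)/B_stable` (%).

All parameters ship with the package
(`src/seagrass_mlr/data/table2_defaults.yaml`); a synthetic-data module
emulates the nine-treatment field shading experiment behind the
acclimation curves so the sigmoid-fitting stage is testable end to end.

## Worked example

```python
from seagrass_mlr import (compute_mlr, find_bistable_region,
                          default_parameters, make_scenario)

params = default_parameters()
for acc in (False, True):
    plain = make_scenario(acclimation=acc, self_facilitation=False, params=params)
    fac = make_scenario(acclimation=acc, self_facilitation=True, params=params)
    print(acc, round(compute_mlr(plain).mlr_percent_si, 2),
          find_bistable_region(fac))
```

prints

```
False 5.74 BistableRegion(lower=5.094645500502786, upper=5.735120687021633, empty=False)
True 3.39 BistableRegion(lower=2.9128684651996832, upper=3.390121014538731, empty=False)
```

i.e. a non-acclimating meadow needs ≈5.7% of surface irradiance to
persist while an acclimating one needs only ≈3.4% — photoacclimation
roughly halves the light threshold. With self-facilitation the
collapse threshold drops further (5.09 / 2.91% SI), but between the two
bounds the meadow is bistable: once lost it will not recover until
light rises back above the upper bound (hysteresis). Under Beer–Lambert
attenuation, halving an MLR deepens the colonization limit by
`ln 2 / k` ≈ 9.9 m in clear water (k = 0.07 m⁻¹) and ≈ 1.2 m in turbid
water (k = 0.57 m⁻¹) — see `seagrass_mlr.depth_limit_change`.

The same analyses are scripted as a numbered pipeline under `analysis/`
(synthetic shading data → sigmoid fits → MLR/bistability → resilience →
biomass-ratio sweep → depth limits), each writing its tables under
`results/`, and as a CLI:

```bash
seagrass-mlr mlr --scenario acclimation
seagrass-mlr bistability --scenario acclimation+facilitation
seagrass-mlr reproduce --out-dir results
```

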