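# Methods

## Model

The state variable is total seagrass biomass density `B` (g DW m⁻²),
aggregating above-ground (ABG) and below-ground (BG) compartments
through a fixed ratio `BAR = BG/ABG`. Its dynamics are

```
dB/dt = K · 1/(1+BAR) · (f_day·P(I) − (R + RRR·BAR)) · B · (1 − B/N) − δ(B)
```

* `P(I) = P_max·I/(I + I_k)` — Michaelis–Menten gross photosynthesis
  (mg O₂ g⁻¹ ABG DW h⁻¹); saturates at `P_max`, half-saturation at the
  saturation irradiance `I_k`.
* `f_day = 0.5` — photosynthesis operates about 12 h per day while
  respiration runs around the clock; exposed as `daylight_fraction` in
  the scenario configuration.
* `R` — above-ground (leaf) respiration; `RRR` — below-ground
  respiration per unit BG biomass, fixed at `R_max/10 = 0.1987`
  mg O₂ g⁻¹ BG DW h⁻¹ in every scenario, including acclimation variants
  and `BAR` sweeps (the below-ground compartment is assumed not to
  acclimate).
* `K = 0.001075` g total DW per mg O₂ — conversion from net oxygen
  evolution to biomass production; `1/(1+BAR)` allocates production
  across compartments per unit total biomass.
* `N = 100` g DW m⁻² — carrying capacity of the logistic self-shading
  term.
* `δ(B)` — mortality; see below.

The irradiance `I` is the instantaneous benthic value during daylight
(µmol quanta m⁻² s⁻¹). Results are reported as percent surface
irradiance with 858.04 µmol quanta m⁻² s⁻¹ ≡ 100% SI, the calibration
of the field shading experiment the parameterization derives from.
Daily averaged light is taken as `½·I`; this approximation only labels
the axis and does not enter the dynamics.

### Unit caveat

The shipped parameter table labels `N` and `B₀` in ABG dry weight while
the persistence analysis treats biomass in total dry weight. The
dynamics depend only on using one consistent biomass unit throughout,
which this package does (g total DW m⁻²); the ambiguity is inherited
from the parameter sources and documented rather than resolved.

### Photoacclimation

In acclimating variants each P–I parameter tracks ambient irradiance
through a four-parameter logistic:

```
θ(I) = θ_high + (θ_low − θ_high)/(1 + exp(λ·(I − y_c)))
```

with shipped values (fitted to a nine-treatment field shading
experiment): `P_max`: 11.64 → 2.096, λ = 0.008524, y_c = −49.1;
`I_k`: 70.048 → 24.544, λ = 0.00863, y_c = 177.458;
`R`: 1.987 → 1.509, λ = 0.4567, y_c = 267.1. The negative `P_max`
midpoint is a legitimate fitted value (the curve's lower shoulder lies
below zero irradiance); λ values are dimensionally inverse irradiance.
Non-acclimating variants hold the three parameters at their high-light
values.

### Mortality and self-facilitation

Without facilitation, `δ(B) = d₀·B` with `d₀ = 0.000116 h⁻¹`. With
facilitation the per-capita rate is damped by
`(1 + e^{−λ_B·B₀})/(1 + e^{λ_B(B − B₀)})` (λ_B = 0.05 per g DW m⁻²,
B₀ = 10 g DW m⁻²), normalized so the multiplier is exactly 1 at
`B = 0`. That normalization has a structural consequence used as a
cross-check everywhere: the bare state's stability boundary is
identical with and without facilitation, so the upper edge of any
bistable window must equal the corresponding plain-mortality MLR.

## Equilibrium analysis

For a 1-D ODE every question reduces to root-finding:

* **Equilibria** (`find_equilibria`): positive roots of the per-capita
  rate are bracketed by a sign scan on a 2001-point biomass grid over
  [0, N] and refined by Brent's method to 10⁻⁸ g DW m⁻². The grid is
  dense enough because the rate function is smooth with at most three
  roots (verified against a 10×-finer brute-force scan on randomized
  draws). `B = 0` is appended analytically, its stability given by the
  sign of the per-capita limit `G₀ − d₀`. Roots are labelled stable or
  unstable by the sign of d(dB/dt)/dB (central difference, step
  10⁻⁷·N); |slope| < 10⁻¹⁰ is labelled `marginal` rather than forced
  into either class.
* **MLR** (`compute_mlr`): the lowest irradiance admitting a strictly
  positive *stable* equilibrium. The criterion function is the
  per-capita rate at `B → 0` (plain mortality) or its maximum over a
  biomass grid (facilitation, where the vegetated branch exists below
  the invasion threshold). Without facilitation the per-capita rate is
  strictly decreasing in `B`, so the two criteria coincide — asserted
  in the tests. The threshold is found by scanning 2000 irradiance
  points over 0.1–100% SI upward for the first sign change, then Brent
  refinement to 0.005% SI. The upward scan matters: with acclimation
  the net rate is *not* monotone in irradiance (the steep respiration
  sigmoid switching on near 267 µmol can close the viability window
  again), and at `BAR = 9` there are three crossings — the MLR is the
  lowest. A single global bisection would be wrong there.
* **Bistable window** (`find_bistable_region`): lower edge = fold =
  facilitated MLR; upper edge = transcritical point = zero of the
  `B → 0` per-capita rate. Both are smooth 1-D crossings refined by
  Brent. Scenarios without facilitation return an empty region.
* **Closed forms**: the plain variant (no acclimation, no facilitation)
  admits `I* = I_k·P*/(P_max − P*)` with
  `P* = (d₀(1+BAR)/K + R + RRR·BAR)/f_day`, and a vegetated equilibrium
  `B* = N(1 − d₀/G₀)`. These are used as independent oracles in the
  tests, never as the implementation path.

## Resilience

`resilience = 100·(B_stable − B_unstable)/B_stable` (%), computed from
the classified equilibria. The ratio is defined only in the bistable
window; it is extended by continuity to 0 where no vegetated state
exists and 100 where the bare state is unstable, which makes the
profile a continuous, monotone sweep from 0 to 100 across the window.
If facilitation ever produced two positive stable states (it does not
with the shipped parameters) the largest stable and largest unstable
points would be used. The statistic is restricted to facilitation
variants: without the mortality feedback no unstable equilibrium exists
and the basin of attraction is unbounded.

## Sigmoid fitting

`fit_sigmoid` minimizes unweighted least squares over
(high, low, slope, inflection) with the Levenberg–Marquardt algorithm
(lmfit), started from the standard logistic heuristic — high = max(y),
low = min(y), inflection = median(x), slope = 4/range(x) — and, because
a steep transition can leave only one or two observations on the ramp,
complemented by a deterministic multi-start (slope scales ×1 and ×100;
inflection candidates at the median and at the two between-level gaps
where the mean response jumps most). The best optimum is then polished
by bounded trust-region least squares with per-column Jacobian scaling:
the steep respiration curve's sum-of-squares surface has a long, badly
scaled valley in (slope, inflection) where unscaled LM stalls a few
percent short of the optimum, and the scaled polish follows the valley
to the floor (noiseless recovery ~10⁻⁸ relative instead of ~10⁻¹).
Box constraints: slope > 0, high/low ∈ [0, 3·max(y)], inflection
unconstrained (fitted midpoints may be negative). Standard errors come
from the curvature at the optimum; a flat response (relative spread
below 10⁻⁸) is flagged unidentifiable instead of fitted. Fits are
per-parameter (three univariate fits), not joint.

## Synthetic shading data

The generator emulates the structure of the field shading experiment
behind the acclimation curves: nine light treatments (74, 60, 42, 32,
26, 25, 16, 10, 4% SI), instantaneous irradiance = %SI share of 858.04,
and per-treatment estimates of `P_max`, `I_k`, `R` drawn as truth-curve
value × unit-mean lognormal noise of stated CV. Defaults: 3 replicates
per treatment and CV = 0.1 — the source experiment's replication and
error magnitudes are published elsewhere, so these are explicit,
clearly-labelled placeholders chosen as typical of field physiology
designs. The generator reproduces the truth exactly at CV = 0 and is
deterministic for a fixed seed.

What passing the pipeline tests shows — and does not show: noiseless
closure (generate → fit → MLR within 0.1% SI of truth) validates the
code path, not the field experiment; with noise, asymptotes the design
actually reaches (all high-light values, the respiration low) recover
to ~5% in the median over 200 replicate draws, while the `I_k`
low-light asymptote sits below the darkest treatment (its value at 4%
SI is 34.8 vs an asymptote of 24.5) and is extrapolation-limited to
~10%; the steep respiration slope λ_R is effectively unidentifiable
under noise (a single ramp point). Real data would share these
identifiability limits.

## Trajectory integrator

Classic fixed-step RK4 on the biomass ODE, default step 1 h (system
rates ≪ 1 h⁻¹; tests use 24 h steps, still far inside the stability
region since per-capita rates are ~10⁻³ h⁻¹). Biomass is clamped at 0
and divergence (non-finite or > 10·N) raises. Used for demonstrations
and to validate equilibrium predictions dynamically (separatrix
property); all equilibrium analysis is root-finding, not integration.

## Problem sizes and determinism

Default resolutions — 2001-point biomass grids, 2000-point irradiance
scans, 160–200-point profile grids, 200 replicate fits in the noisy
recovery study — were chosen so each analysis completes in seconds
while keeping discretization error at least an order of magnitude below
the reported precision (thresholds are refined by bisection to 0.005%
SI and printed to 2 decimals). Every analysis is deterministic given
the parameter file and, where noise is involved, the seed.

## Known limitations

* One-compartment biomass: no separate leaf/rhizome/root state
  variables, no reallocation dynamics; `BAR` is a fixed parameter, not
  a state.
* No temperature dependence, no diel or seasonal light curves, no
  spatial structure or water-column optics beyond a scalar attenuation
  coefficient.
* The acclimation advantage on the MLR holds throughout the
  light-limited regime (`BAR ≤ 9` in the sweep) but reverses by ~1% SI
  at `BAR = 10` without facilitation, where both thresholds approach
  full sun and the acclimated `P_max(I)` still sits marginally below
  its asymptote — a small, real property of the sigmoid
  parameterization worth knowing before quoting the "always better"
  heuristic.
* Resilience here is basin width in biomass only; return times,
  stochastic exit probabilities and potential-landscape metrics are out
  of scope.
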