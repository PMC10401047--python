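"""Ecological resilience of the vegetated state along the light gradient.

Resilience is quantified as the relative size of the biomass perturbation
the vegetated state can absorb without collapsing to bare sand::

    resilience = 100 · (B_stable − B_unstable) / B_stable   [%]

where ``B_stable`` and ``B_unstable`` are the strictly positive stable
and unstable equilibria of the biomass ODE. The ratio is only defined
inside the bistable window; it is extended by continuity to 0 where no
vegetated state exists (any perturbation "collapses" a bare system) and
to 100 where the bare state is unstable (the vegetated state recovers
from any perturbation). The statistic only applies to model variants
with self-facilitation, the mechanism that produces bistability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .equilibria import EquilibriumSet, find_equilibria
from .light import LightReference, percent_surface_irradiance, si_to_instantaneous
from .model import ScenarioConfig

__all__ = ["ResiliencePoint", "resilience_from_equilibria", "resilience_profile"]


@dataclass(frozen=True)
class ResiliencePoint:
    irradiance: float        # µmol quanta m⁻² s⁻¹
    percent_si: float
    resilience: float        # % in [0, 100]
    regime: str              # "bare-only" | "bistable" | "vegetated-only"


def resilience_from_equilibria(equilibria: EquilibriumSet) -> float:
    """Resilience (%) from a classified equilibrium set.

    Bistable sets give ``100·(B_s − B_u)/B_s`` using the largest positive
    stable and largest positive unstable point (fold points labelled
    marginal count as coincident stable/unstable, giving 0); sets with a
    vegetated state but no positive unstable point give 100; sets with
    no vegetated state give 0.
    """
    stable = [p.biomass for p in equilibria.positive_stable]
    unstable = [p.biomass for p in equilibria.positive_unstable]
    marginal = [
        p.biomass for p in equilibria.points if p.stability == "marginal" and p.biomass > 0
    ]
    if not stable:
        return 0.0  # no vegetated state (a marginal fold point has zero basin)
    b_s = max(stable)
    candidates = unstable + marginal
    if not candidates:
        return 100.0
    b_u = max(candidates)
    return 100.0 * (b_s - b_u) / b_s


def resilience_profile(
    scenario: ScenarioConfig,
    si_grid: Sequence[float],
    ref: LightReference | None = None,
) -> list[ResiliencePoint]:
    """Resilience at each %SI value of an ascending light grid.

    Only defined for self-facilitation scenarios (without the mortality
    feedback no unstable equilibrium, and hence no finite basin of
    attraction, exists).
    """
    if not scenario.mortality.self_facilitation:
        raise ValueError(
            "resilience is defined for self-facilitation scenarios only; "
            "without the mortality feedback the system is never bistable"
        )
    si_grid = list(si_grid)
    if si_grid != sorted(si_grid):
        raise ValueError("si_grid must be ascending")
    ref = ref or LightReference()
    out: list[ResiliencePoint] = []
    for si in si_grid:
        irr = si_to_instantaneous(si, ref)
        eq = find_equilibria(irr, scenario)
        if eq.bistable:
            regime = "bistable"
        elif eq.positive_stable:
            regime = "vegetated-only"
        else:
            regime = "bare-only"
        out.append(
            ResiliencePoint(
                irradiance=irr,
                percent_si=percent_surface_irradiance(irr, ref),
                resilience=resilience_from_equilibria(eq),
                regime=regime,
            )
        )
    return out
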