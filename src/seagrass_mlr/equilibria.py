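"""Equilibrium structure of the biomass ODE along the light gradient.

For a one-dimensional ODE the full bifurcation picture is recovered by
root-finding: at each irradiance the equilibria are the zeros of dB/dt
on [0, N], classified stable/unstable by the sign of d(dB/dt)/dB. The
bare state B = 0 is always an equilibrium; its stability is the sign of
the per-capita rate at B → 0. From the classified equilibria follow the
minimum light requirement (MLR: lowest irradiance admitting a strictly
positive stable state), the bistable irradiance window bounded below by
a fold (saddle-node) bifurcation and above by the transcritical point
where the bare state loses stability, and the sensitivity of the MLR to
the below/above-ground biomass ratio.

Because the acclimated net-growth rate need not be monotone in
irradiance (the respiration sigmoid switches on over a narrow light
band), viability thresholds are located by scanning an irradiance grid
upward for the first sign change and refining it by bisection, never by
a single global bisection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .light import LightReference, si_to_instantaneous
from .model import ScenarioConfig, biomass_rate, per_capita_rate

__all__ = [
    "EquilibriumPoint",
    "EquilibriumSet",
    "MLRResult",
    "BistableRegion",
    "find_equilibria",
    "compute_mlr",
    "find_bistable_region",
    "bar_sweep",
    "closed_form_mlr_irradiance",
    "closed_form_positive_equilibrium",
]

#: |slope| below which an equilibrium is labelled marginal (fold point).
MARGINAL_SLOPE = 1e-10


@dataclass(frozen=True)
class EquilibriumPoint:
    biomass: float           # g DW m⁻²
    stability: str           # "stable" | "unstable" | "marginal"


@dataclass(frozen=True)
class EquilibriumSet:
    """Classified equilibria of dB/dt at one irradiance, sorted ascending."""

    irradiance: float
    points: tuple[EquilibriumPoint, ...]

    @property
    def stable(self) -> tuple[EquilibriumPoint, ...]:
        return tuple(p for p in self.points if p.stability == "stable")

    @property
    def unstable(self) -> tuple[EquilibriumPoint, ...]:
        return tuple(p for p in self.points if p.stability == "unstable")

    @property
    def positive_stable(self) -> tuple[EquilibriumPoint, ...]:
        return tuple(p for p in self.stable if p.biomass > 0)

    @property
    def positive_unstable(self) -> tuple[EquilibriumPoint, ...]:
        return tuple(p for p in self.unstable if p.biomass > 0)

    @property
    def bistable(self) -> bool:
        return len(self.stable) >= 2


@dataclass(frozen=True)
class MLRResult:
    """Minimum light requirement in both irradiance units."""

    scenario: str
    mlr_instantaneous: float  # µmol quanta m⁻² s⁻¹
    mlr_percent_si: float     # % SI


@dataclass(frozen=True)
class BistableRegion:
    """Irradiance window with two stable states, in % SI.

    ``lower`` is the fold bifurcation (vegetated state appears), ``upper``
    the transcritical point (bare state destabilizes). ``empty`` marks
    scenarios with no bistability, e.g. without self-facilitation.
    """

    lower: float | None
    upper: float | None
    empty: bool

    def __post_init__(self) -> None:
        if not self.empty and not (self.lower < self.upper):
            raise ValueError("non-empty bistable region requires lower < upper")


def _rate_slope(biomass: float, irradiance: float, scenario: ScenarioConfig) -> float:
    """d(dB/dt)/dB by central difference (one-sided at B = 0)."""
    h = max(1e-7 * scenario.carrying_capacity, 1e-9)
    if biomass == 0.0:
        # dB/dt = B·g(B) ⇒ slope at 0 is the per-capita limit, exactly
        return per_capita_rate(0.0, irradiance, scenario)
    lo = max(biomass - h, 0.0)
    return (
        biomass_rate(biomass + h, irradiance, scenario)
        - biomass_rate(lo, irradiance, scenario)
    ) / (biomass + h - lo)


def _classify(slope: float) -> str:
    if abs(slope) < MARGINAL_SLOPE:
        return "marginal"
    return "stable" if slope < 0 else "unstable"


def find_equilibria(
    irradiance: float,
    scenario: ScenarioConfig,
    resolution: int = 2001,
    tolerance: float = 1e-8,
) -> EquilibriumSet:
    """Locate and classify every equilibrium of dB/dt on [0, N].

    Positive roots are bracketed by a sign scan of the per-capita rate on
    a ``resolution``-point biomass grid (the per-capita rate has the same
    positive roots as dB/dt but is better conditioned near zero) and
    refined by Brent bisection to ``tolerance`` in biomass. B = 0 is
    appended analytically with stability from the per-capita limit.
    """
    if resolution < 100:
        raise ValueError("resolution must be at least 100 grid points")
    n = scenario.carrying_capacity
    grid = np.linspace(0.0, n, resolution)
    vals = per_capita_rate(grid, irradiance, scenario)

    points = [EquilibriumPoint(0.0, _classify(_rate_slope(0.0, irradiance, scenario)))]

    signs = np.sign(vals)
    roots: list[float] = []
    for i in np.nonzero(np.diff(signs) != 0)[0]:
        lo, hi = grid[i], grid[i + 1]
        root = brentq(
            lambda b: per_capita_rate(b, irradiance, scenario),
            lo,
            hi,
            xtol=tolerance,
        )
        roots.append(float(root))
    # exact grid hits (rare) would be skipped by the sign test; catch zeros
    for i in np.nonzero(vals == 0.0)[0]:
        if grid[i] > 0 and not any(abs(grid[i] - r) < 10 * tolerance for r in roots):
            roots.append(float(grid[i]))

    for root in sorted(roots):
        points.append(
            EquilibriumPoint(root, _classify(_rate_slope(root, irradiance, scenario)))
        )
    return EquilibriumSet(irradiance=irradiance, points=tuple(points))


# ---------------------------------------------------------------------------
# viability margins: smooth functions whose zero crossings are the thresholds


def _invasion_margin(scenario: ScenarioConfig) -> Callable[[float], float]:
    """Per-capita rate at B → 0 as a function of irradiance.

    Its sign gives the stability of the bare state (transcritical
    threshold); independent of the facilitation multiplier, which is 1
    at zero biomass.
    """

    def margin(irradiance: float) -> float:
        return per_capita_rate(0.0, irradiance, scenario)

    return margin


def _persistence_margin(
    scenario: ScenarioConfig, resolution: int = 2001
) -> Callable[[float], float]:
    """Max over B ∈ [0, N) of the per-capita rate, as a function of irradiance.

    Positive iff a strictly positive stable equilibrium exists: without
    self-facilitation the per-capita rate is maximal at B → 0, so this
    reduces to the invasion margin; with self-facilitation the interior
    maximum detects the vegetated branch beyond the fold.
    """
    grid = np.linspace(0.0, scenario.carrying_capacity, resolution, endpoint=False)

    def margin(irradiance: float) -> float:
        return float(np.max(per_capita_rate(grid, irradiance, scenario)))

    return margin


def _first_upward_crossing(
    margin: Callable[[float], float],
    si_grid: np.ndarray,
    ref: LightReference,
    tolerance_si: float,
) -> float | None:
    """Lowest %SI where ``margin`` turns positive, refined by bisection.

    Scans the grid upward; returns None when the margin never turns
    positive. Raises if the margin is already positive at the bracket's
    lower edge (the bracket does not straddle the threshold).
    """
    vals = np.array([margin(si_to_instantaneous(si, ref)) for si in si_grid])
    if vals[0] > 0:
        raise ValueError(
            f"viability margin already positive at {si_grid[0]:.3g}% SI; "
            "lower the bracket start"
        )
    pos = np.nonzero(vals > 0)[0]
    if pos.size == 0:
        return None
    i = pos[0]
    root = brentq(
        lambda si: margin(si_to_instantaneous(si, ref)),
        si_grid[i - 1],
        si_grid[i],
        xtol=tolerance_si,
    )
    return float(root)


def compute_mlr(
    scenario: ScenarioConfig,
    si_bracket: tuple[float, float] = (0.1, 100.0),
    tolerance: float = 0.005,
    ref: LightReference | None = None,
    scan_points: int = 2000,
) -> MLRResult:
    """Minimum light requirement: lowest irradiance with a vegetated state.

    Operationally the smallest irradiance at which a strictly positive
    stable equilibrium exists, i.e. where the persistence margin (max
    over biomass of the per-capita rate) first turns positive. For
    scenarios without self-facilitation this coincides with the
    transcritical condition at B → 0. ``tolerance`` is in % SI.
    """
    ref = ref or LightReference()
    if scenario.mortality.self_facilitation:
        margin = _persistence_margin(scenario)
    else:
        margin = _invasion_margin(scenario)
    si_grid = np.linspace(si_bracket[0], si_bracket[1], scan_points)
    root = _first_upward_crossing(margin, si_grid, ref, tolerance)
    if root is None:
        raise ValueError(
            f"no viable light level for {scenario.label} within "
            f"{si_bracket[0]}-{si_bracket[1]}% SI"
        )
    return MLRResult(
        scenario=scenario.label,
        mlr_instantaneous=si_to_instantaneous(root, ref),
        mlr_percent_si=root,
    )


def find_bistable_region(
    scenario: ScenarioConfig,
    si_bracket: tuple[float, float] = (0.1, 100.0),
    tolerance: float = 0.005,
    ref: LightReference | None = None,
    scan_points: int = 2000,
) -> BistableRegion:
    """Irradiance window with two stable states (vegetated and bare).

    The lower edge is the fold where the vegetated branch appears while
    the bare state is still stable (persistence margin crosses zero);
    the upper edge is the transcritical point where the bare state
    destabilizes (invasion margin crosses zero). Scenarios without
    self-facilitation return an empty region: there the two margins
    coincide, so the window has zero width.
    """
    ref = ref or LightReference()
    if not scenario.mortality.self_facilitation:
        return BistableRegion(lower=None, upper=None, empty=True)
    si_grid = np.linspace(si_bracket[0], si_bracket[1], scan_points)
    lower = _first_upward_crossing(_persistence_margin(scenario), si_grid, ref, tolerance)
    upper = _first_upward_crossing(_invasion_margin(scenario), si_grid, ref, tolerance)
    if lower is None or upper is None or not lower < upper - tolerance:
        return BistableRegion(lower=None, upper=None, empty=True)
    return BistableRegion(lower=lower, upper=upper, empty=False)


def bar_sweep(
    scenario: ScenarioConfig,
    bar_values: Sequence[float] = tuple(range(1, 11)),
    tolerance: float = 0.005,
    ref: LightReference | None = None,
) -> list[tuple[float, MLRResult | None]]:
    """MLR as a function of the below/above-ground biomass ratio.

    All other parameters, including the below-ground respiration rate,
    stay at their defaults. Ratios with no viable light level at or
    below full sun yield ``None`` instead of a number.
    """
    bar_values = list(bar_values)
    if any(b <= 0 for b in bar_values) or sorted(bar_values) != bar_values:
        raise ValueError("bar_values must be positive and ascending")
    out: list[tuple[float, MLRResult | None]] = []
    for bar in bar_values:
        try:
            res = compute_mlr(scenario.with_bar(bar), tolerance=tolerance, ref=ref)
        except ValueError:
            res = None
        out.append((float(bar), res))
    return out


# ---------------------------------------------------------------------------
# closed forms for the variant without acclimation or self-facilitation


def closed_form_mlr_irradiance(scenario: ScenarioConfig) -> float:
    """Analytic MLR irradiance for constant P–I parameters, no facilitation.

    Setting the B → 0 per-capita rate to zero and inverting the
    Michaelis–Menten light response gives ``I* = I_k·P*/(P_max − P*)``
    with ``P* = (d0·(1+BAR)/K + R + RRR·BAR)/f_day``. Used as an
    independent oracle for the numerical threshold search.
    """
    if scenario.acclimation or scenario.mortality.self_facilitation:
        raise ValueError("closed form requires constant P–I and plain mortality")
    pi = scenario.static_pi
    p_star = (
        scenario.mortality.d0 * (1.0 + scenario.bar) / scenario.conversion_k
        + pi.r
        + scenario.rrr * scenario.bar
    ) / scenario.daylight_fraction
    if p_star >= pi.pmax:
        raise ValueError("demand exceeds P_max: no viable irradiance exists")
    return pi.ik * p_star / (pi.pmax - p_star)


def closed_form_positive_equilibrium(
    irradiance: float, scenario: ScenarioConfig
) -> float | None:
    """Analytic vegetated equilibrium ``B* = N·(1 − d0/G₀)`` (no facilitation).

    ``G₀`` is the per-capita net production at vanishing biomass; returns
    None when the bare state is the only equilibrium (G₀ ≤ d0).
    """
    if scenario.mortality.self_facilitation:
        raise ValueError("closed form requires plain mortality")
    g0 = per_capita_rate(0.0, irradiance, scenario) + scenario.mortality.d0
    if g0 <= scenario.mortality.d0:
        return None
    return scenario.carrying_capacity * (1.0 - scenario.mortality.d0 / g0)
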