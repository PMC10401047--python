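"""Core carbon-balance model for a seagrass meadow on a light gradient.

The state variable is total (above- plus below-ground) biomass density
``B`` (g DW m⁻²), governed by a single ODE that balances photosynthetic
gain against respiration and mortality::

    dB/dt = K · 1/(1+BAR) · (½·P − (R + RRR·BAR)) · B · (1 − B/N) − δ(B)

where ``P`` is gross photosynthesis (Michaelis–Menten in irradiance),
``R`` above-ground respiration, ``RRR`` below-ground respiration per unit
below-ground biomass, ``BAR`` the below- to above-ground biomass ratio,
``K`` a biomass-per-oxygen conversion efficiency, ``N`` the carrying
capacity and ``δ`` a mortality term. The ½ in front of ``P`` accounts for
photosynthesis running only during daylight (12 h of 24 h) while
respiration runs around the clock.

Two switchable mechanisms give four model variants:

* **photoacclimation** — the photosynthesis–irradiance (P–I) parameters
  ``P_max``, ``I_k`` and ``R`` follow sigmoid functions of the ambient
  irradiance instead of staying at their high-light values;
* **self-facilitation** — per-capita mortality declines with standing
  biomass (clonal integration), which can create bistability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PIParameters",
    "SigmoidResponse",
    "AcclimationModel",
    "MortalityParams",
    "ScenarioConfig",
    "gross_photosynthesis",
    "sigmoid_response",
    "effective_pi_parameters",
    "facilitation_multiplier",
    "mortality_loss",
    "biomass_rate",
    "per_capita_rate",
]

#: Fraction of the day during which photosynthesis operates (12 h / 24 h).
DAYLIGHT_FRACTION = 0.5


@dataclass(frozen=True)
class PIParameters:
    """Photosynthesis–irradiance parameters at a fixed acclimation state.

    Attributes
    ----------
    pmax : float
        Maximum gross photosynthetic rate, mg O₂ g⁻¹ ABG DW h⁻¹.
    ik : float
        Saturation irradiance, µmol quanta m⁻² s⁻¹.
    r : float
        Above-ground (leaf) respiration, mg O₂ g⁻¹ ABG DW h⁻¹.
    """

    pmax: float
    ik: float
    r: float

    def __post_init__(self) -> None:
        if not (self.pmax > 0 and self.ik > 0 and self.r > 0):
            raise ValueError(
                f"P–I parameters must be strictly positive, got "
                f"pmax={self.pmax}, ik={self.ik}, r={self.r}"
            )


@dataclass(frozen=True)
class SigmoidResponse:
    """Four-parameter logistic response of one P–I parameter to irradiance.

    Evaluates to ``high + (low − high) / (1 + exp(slope·(I − inflection)))``:
    the parameter approaches ``high`` under saturating light and ``low``
    under strong shading, with the transition centred at ``inflection``
    and steepness ``slope``.
    """

    high: float
    low: float
    slope: float          # (µmol quanta m⁻² s⁻¹)⁻¹
    inflection: float     # µmol quanta m⁻² s⁻¹; may be negative (fitted)

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"sigmoid slope must be > 0, got {self.slope}")

    def __call__(self, irradiance):
        return sigmoid_response(irradiance, self)


@dataclass(frozen=True)
class AcclimationModel:
    """Bundle of the three sigmoid responses defining photoacclimation."""

    pmax_curve: SigmoidResponse
    ik_curve: SigmoidResponse
    resp_curve: SigmoidResponse


@dataclass(frozen=True)
class MortalityParams:
    """Mortality term parameters.

    With ``self_facilitation`` off the loss is simply ``d0·B``. With it
    on, the per-capita rate is multiplied by a factor that equals 1 at
    ``B = 0`` and declines sigmoidally as biomass builds past ``b0``,
    representing reduced mortality in dense, clonally integrated meadows.
    """

    d0: float                     # h⁻¹
    self_facilitation: bool = False
    lambda_b: float = 0.05        # (g DW m⁻²)⁻¹
    b0: float = 10.0              # g DW m⁻²

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError(f"d0 must be > 0, got {self.d0}")
        if self.self_facilitation and not (self.lambda_b > 0 and self.b0 > 0):
            raise ValueError(
                "lambda_b and b0 must be > 0 when self-facilitation is on"
            )


@dataclass(frozen=True)
class ScenarioConfig:
    """One of the four model variants plus all shared constants.

    ``acclimation`` selects whether the P–I parameters track irradiance
    through ``acclimation_model`` or stay fixed at ``static_pi``;
    ``mortality.self_facilitation`` selects the mortality law.
    """

    acclimation: bool
    mortality: MortalityParams
    static_pi: PIParameters
    acclimation_model: AcclimationModel | None = None
    conversion_k: float = 0.001075    # g total DW per mg O₂
    carrying_capacity: float = 100.0  # g DW m⁻²
    bar: float = 1.0                  # below/above-ground biomass ratio
    rrr: float = 0.1987               # mg O₂ g⁻¹ BG DW h⁻¹
    daylight_fraction: float = DAYLIGHT_FRACTION

    def __post_init__(self) -> None:
        if not (self.conversion_k > 0 and self.carrying_capacity > 0):
            raise ValueError("conversion_k and carrying_capacity must be > 0")
        if self.bar < 0 or self.rrr < 0:
            raise ValueError("bar and rrr must be non-negative")
        if self.acclimation and self.acclimation_model is None:
            raise ValueError("acclimation scenario requires an acclimation_model")

    def with_bar(self, bar: float) -> "ScenarioConfig":
        """Copy of this scenario with a different biomass ratio."""
        return replace(self, bar=bar)

    @property
    def label(self) -> str:
        acc = "acclimation" if self.acclimation else "non-acclimation"
        fac = "self-facilitation" if self.mortality.self_facilitation else "no-self-facilitation"
        return f"{acc}/{fac}"


def gross_photosynthesis(irradiance, params: PIParameters):
    """Michaelis–Menten gross photosynthesis ``P_max·I/(I + I_k)``.

    Saturates at ``pmax`` and reaches half of it at ``I = ik``. Accepts
    scalar or array irradiance (µmol quanta m⁻² s⁻¹); negative values
    are rejected.
    """
    irradiance = np.asarray(irradiance, dtype=float)
    if np.any(irradiance < 0):
        raise ValueError("irradiance must be non-negative")
    out = params.pmax * irradiance / (irradiance + params.ik)
    return out.item() if out.ndim == 0 else out


def sigmoid_response(irradiance, curve: SigmoidResponse):
    """Evaluate a four-parameter logistic acclimation curve.

    Tends to ``curve.high`` as ``I → +∞`` and to ``curve.low`` as
    ``I → −∞``; any real irradiance is accepted so limits can be probed.
    """
    irradiance = np.asarray(irradiance, dtype=float)
    # exp overflows harmlessly to inf for very negative I·slope; suppress
    with np.errstate(over="ignore"):
        expo = np.exp(curve.slope * (irradiance - curve.inflection))
    out = curve.high + (curve.low - curve.high) / (1.0 + expo)
    return out.item() if out.ndim == 0 else out


def effective_pi_parameters(irradiance: float, scenario: ScenarioConfig) -> PIParameters:
    """P–I parameters in effect at the given irradiance.

    Returns ``static_pi`` unchanged when acclimation is off; otherwise
    evaluates the three sigmoid curves at the ambient irradiance.
    """
    if irradiance < 0:
        raise ValueError("irradiance must be non-negative")
    if not scenario.acclimation:
        return scenario.static_pi
    acc = scenario.acclimation_model
    return PIParameters(
        pmax=sigmoid_response(irradiance, acc.pmax_curve),
        ik=sigmoid_response(irradiance, acc.ik_curve),
        r=sigmoid_response(irradiance, acc.resp_curve),
    )


def facilitation_multiplier(biomass, params: MortalityParams):
    """Mortality reduction factor ``(1 + e^{−λ_B·B₀}) / (1 + e^{λ_B(B − B₀)})``.

    Equals 1 exactly at ``B = 0``, is strictly decreasing in biomass and
    stays positive, so facilitated mortality never exceeds ``d0·B``.
    Returns 1 identically when self-facilitation is off.
    """
    biomass = np.asarray(biomass, dtype=float)
    if not params.self_facilitation:
        out = np.ones_like(biomass)
        return out.item() if out.ndim == 0 else out
    num = 1.0 + math.exp(-params.lambda_b * params.b0)
    with np.errstate(over="ignore"):
        den = 1.0 + np.exp(params.lambda_b * (biomass - params.b0))
    out = num / den
    return out.item() if out.ndim == 0 else out


def mortality_loss(biomass, params: MortalityParams):
    """Biomass loss rate ``δ(B)`` in g DW m⁻² h⁻¹.

    ``d0·B`` without self-facilitation; with it, the per-capita rate is
    damped by :func:`facilitation_multiplier`.
    """
    biomass = np.asarray(biomass, dtype=float)
    if np.any(biomass < 0):
        raise ValueError("biomass must be non-negative")
    out = facilitation_multiplier(biomass, params) * params.d0 * biomass
    return out.item() if out.ndim == 0 else out


def _net_growth_coefficient(irradiance: float, scenario: ScenarioConfig) -> float:
    """Per-capita net production at vanishing biomass (no mortality), h⁻¹.

    ``G₀ = K/(1+BAR) · (f_day·P − R − RRR·BAR)`` — the growth side of the
    per-capita balance before the logistic self-shading factor.
    """
    pi = effective_pi_parameters(irradiance, scenario)
    p = gross_photosynthesis(irradiance, pi)
    return (
        scenario.conversion_k
        / (1.0 + scenario.bar)
        * (scenario.daylight_fraction * p - (pi.r + scenario.rrr * scenario.bar))
    )


def per_capita_rate(biomass, irradiance: float, scenario: ScenarioConfig):
    """Per-capita biomass rate of change ``(dB/dt)/B`` in h⁻¹.

    Defined by continuity at ``B = 0`` as the analytic limit
    ``G₀ − d0`` (the facilitation multiplier is exactly 1 there). The
    sign of this quantity at ``B → 0`` decides whether the bare state
    can be invaded. Accepts scalar or array biomass.
    """
    biomass = np.asarray(biomass, dtype=float)
    if np.any(biomass < 0):
        raise ValueError("biomass must be non-negative")
    g0 = _net_growth_coefficient(irradiance, scenario)
    out = (
        g0 * (1.0 - biomass / scenario.carrying_capacity)
        - scenario.mortality.d0 * facilitation_multiplier(biomass, scenario.mortality)
    )
    return out.item() if out.ndim == 0 else out


def biomass_rate(biomass, irradiance: float, scenario: ScenarioConfig):
    """Total biomass rate of change ``dB/dt`` in g DW m⁻² h⁻¹.

    Exactly zero at ``B = 0`` (the bare state is always an equilibrium).
    Biomass above carrying capacity is allowed; the logistic factor then
    makes production negative.
    """
    biomass = np.asarray(biomass, dtype=float)
    if np.any(np.isnan(biomass)) or math.isnan(irradiance):
        raise ValueError("NaN inputs are not allowed")
    out = biomass * np.asarray(per_capita_rate(biomass, irradiance, scenario))
    return out.item() if out.ndim == 0 else out
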