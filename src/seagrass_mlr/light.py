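"""Light-unit conversions: %SI, daily dose, and Beer–Lambert depth limits.

All irradiance bookkeeping in the models runs on instantaneous benthic
irradiance (µmol quanta m⁻² s⁻¹). Results are reported as percent
surface irradiance (%SI) against a fixed full-sun reference, the
convention used for field minimum-light-requirement estimates. Daily
averaged light is approximated as half the daylight instantaneous value,
since photosynthesis sees light for roughly 12 of 24 hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LightReference",
    "percent_surface_irradiance",
    "si_to_instantaneous",
    "instantaneous_to_daily",
    "depth_limit_change",
]


@dataclass(frozen=True)
class LightReference:
    """Anchors for converting between light units.

    ``full_sun_instantaneous`` is the instantaneous irradiance taken to
    equal 100% SI (default 858.04 µmol quanta m⁻² s⁻¹, from the field
    calibration of the shading experiment this model is parameterized
    against); ``daylight_fraction`` is the fraction of the day with
    photosynthetically active light.
    """

    full_sun_instantaneous: float = 858.04
    daylight_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.full_sun_instantaneous > 0:
            raise ValueError("full_sun_instantaneous must be > 0")
        if not 0 < self.daylight_fraction <= 1:
            raise ValueError("daylight_fraction must be in (0, 1]")


_DEFAULT_REF = LightReference()


def percent_surface_irradiance(instantaneous, ref: LightReference = _DEFAULT_REF):
    """Convert instantaneous irradiance to percent surface irradiance."""
    instantaneous = np.asarray(instantaneous, dtype=float)
    if np.any(instantaneous < 0):
        raise ValueError("irradiance must be non-negative")
    out = 100.0 * instantaneous / ref.full_sun_instantaneous
    return out.item() if out.ndim == 0 else out


def si_to_instantaneous(percent_si, ref: LightReference = _DEFAULT_REF):
    """Inverse of :func:`percent_surface_irradiance`."""
    percent_si = np.asarray(percent_si, dtype=float)
    if np.any(percent_si < 0):
        raise ValueError("percent SI must be non-negative")
    out = percent_si * ref.full_sun_instantaneous / 100.0
    return out.item() if out.ndim == 0 else out


def instantaneous_to_daily(instantaneous, ref: LightReference = _DEFAULT_REF):
    """Daily averaged light ≈ daylight_fraction × instantaneous irradiance.

    This is the stated half-rule approximation relating the shading
    experiment's daily dose scale to the instantaneous irradiance used
    by the model; it carries the dose interpretation only approximately
    and does not affect %SI values.
    """
    instantaneous = np.asarray(instantaneous, dtype=float)
    if np.any(instantaneous < 0):
        raise ValueError("irradiance must be non-negative")
    out = ref.daylight_fraction * instantaneous
    return out.item() if out.ndim == 0 else out


def depth_limit_change(mlr_ratio: float, attenuation_k: float) -> float:
    """Depth-limit gain (m) from reducing the MLR by a given factor.

    Under Beer–Lambert attenuation ``I(z) = I₀·e^{−k·z}``, a species
    whose minimum light requirement drops by factor ``mlr_ratio`` (e.g.
    0.5 for a halving) can colonize ``ln(1/mlr_ratio)/k`` metres deeper,
    where ``attenuation_k`` is the diffuse attenuation coefficient (m⁻¹).
    """
    if not mlr_ratio > 0:
        raise ValueError("mlr_ratio must be > 0")
    if not attenuation_k > 0:
        raise ValueError("attenuation_k must be > 0")
    return math.log(1.0 / mlr_ratio) / attenuation_k
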