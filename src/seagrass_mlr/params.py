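"""Parameter configuration: YAML loading, defaults, scenario construction.

The package ships a default parameter file (``data/table2_defaults.yaml``)
holding the Cymodocea nodosa field parameterization; every analysis can
be re-run against a user YAML with the same schema, e.g. one produced by
the acclimation-fitting stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .light import LightReference
from .model import (
    AcclimationModel,
    MortalityParams,
    PIParameters,
    ScenarioConfig,
    SigmoidResponse,
)

__all__ = [
    "ParameterSet",
    "load_parameters",
    "default_parameters",
    "make_scenario",
    "dump_acclimation_yaml",
]


@dataclass(frozen=True)
class ParameterSet:
    """Fully parsed parameter file: everything needed to build scenarios."""

    light: LightReference
    static_pi: PIParameters
    acclimation: AcclimationModel
    bar: float
    rrr: float
    conversion_k: float
    carrying_capacity: float
    d0: float
    lambda_b: float
    b0: float


def _curve(block: dict) -> SigmoidResponse:
    return SigmoidResponse(
        high=float(block["high"]),
        low=float(block["low"]),
        slope=float(block["slope"]),
        inflection=float(block["inflection"]),
    )


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a parameter YAML; ``None`` loads the shipped defaults."""
    if path is None:
        text = (
            resources.files("seagrass_mlr").joinpath("data/table2_defaults.yaml")
        ).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)

    try:
        lr = raw["light_reference"]
        na = raw["non_acclimation"]
        ac = raw["acclimation"]
        bg = raw["below_ground"]
        gm = raw["biomass_growth_mortality"]
    except KeyError as exc:  # pragma: no cover - schema guard
        raise KeyError(f"parameter file missing section {exc}") from exc

    return ParameterSet(
        light=LightReference(
            full_sun_instantaneous=float(lr["full_sun_instantaneous"]),
            daylight_fraction=float(lr["daylight_fraction"]),
        ),
        static_pi=PIParameters(
            pmax=float(na["pmax"]), ik=float(na["ik"]), r=float(na["r"])
        ),
        acclimation=AcclimationModel(
            pmax_curve=_curve(ac["pmax"]),
            ik_curve=_curve(ac["ik"]),
            resp_curve=_curve(ac["r"]),
        ),
        bar=float(bg["bar"]),
        rrr=float(bg["rrr"]),
        conversion_k=float(gm["conversion_k"]),
        carrying_capacity=float(gm["carrying_capacity"]),
        d0=float(gm["d0"]),
        lambda_b=float(gm["lambda_b"]),
        b0=float(gm["b0"]),
    )


def default_parameters() -> ParameterSet:
    """The shipped Cymodocea nodosa field parameterization."""
    return load_parameters(None)


def make_scenario(
    acclimation: bool,
    self_facilitation: bool,
    params: ParameterSet | None = None,
    bar: float | None = None,
) -> ScenarioConfig:
    """Build one of the four model variants from a parameter set.

    ``bar`` overrides the below/above-ground biomass ratio while holding
    every other parameter (including the below-ground respiration rate)
    fixed, as in the biomass-ratio sensitivity sweep.
    """
    p = params or default_parameters()
    return ScenarioConfig(
        acclimation=acclimation,
        mortality=MortalityParams(
            d0=p.d0,
            self_facilitation=self_facilitation,
            lambda_b=p.lambda_b,
            b0=p.b0,
        ),
        static_pi=p.static_pi,
        acclimation_model=p.acclimation,
        conversion_k=p.conversion_k,
        carrying_capacity=p.carrying_capacity,
        bar=p.bar if bar is None else float(bar),
        rrr=p.rrr,
        daylight_fraction=p.light.daylight_fraction,
    )


def dump_acclimation_yaml(model: AcclimationModel, base: ParameterSet | None = None) -> str:
    """Serialize a fitted acclimation model to the parameter-file schema.

    The output is a complete parameter file (fitted sigmoids spliced into
    the default constants), so it can be loaded back by
    :func:`load_parameters` and used as a drop-in replacement.
    """
    p = base or default_parameters()

    def block(c: SigmoidResponse) -> dict:
        return {
            "high": float(c.high),
            "low": float(c.low),
            "slope": float(c.slope),
            "inflection": float(c.inflection),
        }

    doc = {
        "light_reference": {
            "full_sun_instantaneous": p.light.full_sun_instantaneous,
            "daylight_fraction": p.light.daylight_fraction,
        },
        "non_acclimation": {
            "pmax": float(model.pmax_curve.high),
            "ik": float(model.ik_curve.high),
            "r": float(model.resp_curve.high),
        },
        "acclimation": {
            "pmax": block(model.pmax_curve),
            "ik": block(model.ik_curve),
            "r": block(model.resp_curve),
        },
        "below_ground": {"bar": p.bar, "rrr": p.rrr},
        "biomass_growth_mortality": {
            "conversion_k": p.conversion_k,
            "carrying_capacity": p.carrying_capacity,
            "d0": p.d0,
            "lambda_b": p.lambda_b,
            "b0": p.b0,
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)
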