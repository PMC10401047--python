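import pytest

from seagrass_mlr import default_parameters, make_scenario


@pytest.fixture(scope="session")
def params():
    """The shipped Cymodocea nodosa field parameterization."""
    return default_parameters()


@pytest.fixture(scope="session")
def ref(params):
    return params.light


@pytest.fixture(scope="session")
def scenario_factory(params):
    """Build any of the four model variants (optionally at another BAR)."""

    def build(acclimation: bool, self_facilitation: bool, bar: float | None = None):
        return make_scenario(acclimation, self_facilitation, params=params, bar=bar)

    return build


@pytest.fixture(scope="session")
def base_scenario(scenario_factory):
    """No acclimation, no self-facilitation: the analytically solvable variant."""
    return scenario_factory(False, False)
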