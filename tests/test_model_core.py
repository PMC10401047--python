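"""Rate functions of the biomass ODE: identities, limits and shape properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seagrass_mlr import (
    MortalityParams,
    PIParameters,
    SigmoidResponse,
    biomass_rate,
    closed_form_mlr_irradiance,
    effective_pi_parameters,
    facilitation_multiplier,
    gross_photosynthesis,
    mortality_loss,
    per_capita_rate,
    sigmoid_response,
)

PI = PIParameters(pmax=11.64, ik=70.04809, r=1.987)


class TestGrossPhotosynthesis:
    @pytest.mark.parametrize(
        "irradiance, expected",
        [
            (0.0, 0.0),                      # no light, no photosynthesis
            (70.04809, 11.64 / 2),           # half-saturation at I = I_k
            (858.04, 11.64 * 858.04 / 928.08809),  # full sun, near P_max
        ],
    )
    def test_known_values(self, irradiance, expected):
        assert gross_photosynthesis(irradiance, PI) == pytest.approx(expected, rel=1e-12)

    def test_monotone_increasing_and_concave(self):
        grid = np.linspace(0.0, 2000.0, 500)
        p = gross_photosynthesis(grid, PI)
        assert np.all(np.diff(p) > 0)
        assert np.all(np.diff(p, 2) < 0)
        assert np.all(p < PI.pmax)

    def test_negative_irradiance_rejected(self):
        with pytest.raises(ValueError):
            gross_photosynthesis(-1.0, PI)


class TestSigmoidResponse:
    RESP = SigmoidResponse(high=1.987, low=1.509, slope=0.4567, inflection=267.1)
    PMAX = SigmoidResponse(high=11.64, low=2.096, slope=0.008524, inflection=-49.1)

    def test_midpoint_identity(self):
        # at the inflection irradiance the curve sits exactly halfway
        assert sigmoid_response(267.1, self.RESP) == pytest.approx(1.748, abs=1e-12)

    def test_full_sun_approaches_high_light_value(self):
        assert sigmoid_response(858.04, self.PMAX) == pytest.approx(11.64, abs=0.01)

    def test_limits(self):
        assert sigmoid_response(1e9, self.RESP) == pytest.approx(self.RESP.high)
        assert sigmoid_response(-1e9, self.RESP) == pytest.approx(self.RESP.low)

    @settings(deadline=None, derandomize=True)
    @given(
        irradiance=st.floats(-1e4, 1e4),
        high=st.floats(0.1, 100.0),
        low=st.floats(0.1, 100.0),
        slope=st.floats(1e-4, 1.0),
        inflection=st.floats(-500.0, 1000.0),
    )
    def test_value_bounded_by_low_and_high(
        self, irradiance, high, low, slope, inflection
    ):
        if high == low:
            return
        curve = SigmoidResponse(high=high, low=low, slope=slope, inflection=inflection)
        v = sigmoid_response(irradiance, curve)
        # rounding at saturation may overshoot the asymptote by ~1 ulp
        slack = 4 * np.spacing(max(abs(low), abs(high)))
        assert min(low, high) - slack <= v <= max(low, high) + slack
        # strictly inside the range wherever the exponential has not
        # saturated in double precision
        if abs(slope * (irradiance - inflection)) < 30:
            assert min(low, high) < v < max(low, high)

    def test_monotone_with_sign_of_high_minus_low(self):
        grid = np.linspace(-500.0, 1500.0, 400)
        increasing = sigmoid_response(grid, self.PMAX)  # high > low
        assert np.all(np.diff(increasing) > 0)
        flipped = SigmoidResponse(high=2.0, low=8.0, slope=0.01, inflection=100.0)
        assert np.all(np.diff(sigmoid_response(grid, flipped)) < 0)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            SigmoidResponse(high=1.0, low=0.5, slope=0.0, inflection=10.0)


class TestEffectivePIParameters:
    def test_static_without_acclimation(self, base_scenario):
        for irr in (0.0, 50.0, 858.04):
            assert effective_pi_parameters(irr, base_scenario) is base_scenario.static_pi

    def test_high_light_limit_with_acclimation(self, scenario_factory):
        pi = effective_pi_parameters(5000.0, scenario_factory(True, False))
        assert pi.pmax == pytest.approx(11.64, abs=1e-6)
        assert pi.ik == pytest.approx(70.04809, abs=1e-6)
        assert pi.r == pytest.approx(1.987, abs=1e-6)

    def test_darkness_bounded_by_curve_range(self, scenario_factory, params):
        pi = effective_pi_parameters(0.0, scenario_factory(True, False))
        acc = params.acclimation
        for value, curve in [
            (pi.pmax, acc.pmax_curve),
            (pi.ik, acc.ik_curve),
            (pi.r, acc.resp_curve),
        ]:
            # the steep respiration curve saturates to its low value in
            # double precision already at I = 0
            assert min(curve.low, curve.high) <= value <= max(curve.low, curve.high)
        assert pi.pmax < acc.pmax_curve.high and pi.ik < acc.ik_curve.high


class TestMortality:
    PLAIN = MortalityParams(d0=0.000116)
    FACIL = MortalityParams(d0=0.000116, self_facilitation=True, lambda_b=0.05, b0=10.0)

    def test_zero_biomass_zero_loss(self):
        assert mortality_loss(0.0, self.PLAIN) == 0.0
        assert mortality_loss(0.0, self.FACIL) == 0.0

    def test_plain_loss_is_linear(self):
        assert mortality_loss(100.0, self.PLAIN) == pytest.approx(0.0116)

    def test_multiplier_at_threshold_biomass(self):
        # at B = B0 the multiplier is (1 + e^{-λB·B0})/2
        expected = (1.0 + math.exp(-0.5)) / 2.0
        assert facilitation_multiplier(10.0, self.FACIL) == pytest.approx(expected, rel=1e-12)

    def test_multiplier_is_one_at_zero_exactly(self):
        assert facilitation_multiplier(0.0, self.FACIL) == 1.0

    def test_multiplier_decreasing_and_loss_bounded(self):
        b = np.linspace(0.0, 200.0, 400)
        m = facilitation_multiplier(b, self.FACIL)
        assert np.all(np.diff(m) < 0)
        assert np.all(m > 0)
        assert np.all(mortality_loss(b, self.FACIL) <= self.PLAIN.d0 * b + 1e-18)

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValueError):
            mortality_loss(-1.0, self.PLAIN)

    def test_facilitation_requires_positive_shape_parameters(self):
        with pytest.raises(ValueError):
            MortalityParams(d0=1e-4, self_facilitation=True, lambda_b=-0.05, b0=10.0)


class TestBiomassRate:
    def test_bare_state_is_exact_equilibrium(self, scenario_factory):
        for acc in (False, True):
            for fac in (False, True):
                s = scenario_factory(acc, fac)
                for irr in (0.0, 30.0, 100.0, 858.04):
                    assert biomass_rate(0.0, irr, s) == 0.0

    def test_rate_at_carrying_capacity_is_pure_mortality(self, base_scenario):
        n = base_scenario.carrying_capacity
        expected = -base_scenario.mortality.d0 * n
        assert biomass_rate(n, 200.0, base_scenario) == pytest.approx(expected, rel=1e-12)

    def test_rate_negative_above_carrying_capacity(self, base_scenario):
        assert biomass_rate(150.0, 858.04, base_scenario) < 0

    def test_per_capita_vanishes_at_closed_form_threshold(self, base_scenario):
        # I* from inverting the Michaelis-Menten balance at B -> 0
        i_star = closed_form_mlr_irradiance(base_scenario)
        assert per_capita_rate(0.0, i_star, base_scenario) == pytest.approx(0.0, abs=1e-12)

    def test_nan_rejected(self, base_scenario):
        with pytest.raises(ValueError):
            biomass_rate(float("nan"), 100.0, base_scenario)
        with pytest.raises(ValueError):
            biomass_rate(1.0, float("nan"), base_scenario)


class TestPerCapitaRate:
    def test_continuous_at_zero_biomass(self, scenario_factory):
        for fac in (False, True):
            s = scenario_factory(False, fac)
            at_zero = per_capita_rate(0.0, 60.0, s)
            near_zero = per_capita_rate(1e-8, 60.0, s)
            assert near_zero == pytest.approx(at_zero, rel=1e-6)

    def test_strictly_decreasing_without_facilitation(self, base_scenario):
        b = np.linspace(0.0, 100.0, 300)
        rates = per_capita_rate(b, 100.0, base_scenario)
        assert np.all(np.diff(rates) < 0)

    def test_interior_maximum_with_facilitation_in_bistable_window(
        self, scenario_factory, ref
    ):
        # at 5.5% SI the facilitation term outweighs self-shading at low B
        s = scenario_factory(False, True)
        irr = 5.5 / 100.0 * ref.full_sun_instantaneous
        b = np.linspace(0.0, 100.0, 2000)
        rates = per_capita_rate(b, irr, s)
        peak = int(np.argmax(rates))
        assert 0 < peak < len(b) - 1
        assert rates[peak] > rates[0]

    def test_acclimation_helps_at_low_light(self, scenario_factory):
        # below ~50 umol the sigmoid-adjusted physiology yields a better
        # carbon balance at vanishing biomass than the fixed high-light one
        acc = scenario_factory(True, False)
        non = scenario_factory(False, False)
        for irr in (5.0, 15.0, 30.0, 50.0):
            assert per_capita_rate(0.0, irr, acc) >= per_capita_rate(0.0, irr, non)
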