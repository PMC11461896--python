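"""Diffusive flux, residence time, and zero-order attenuation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from glacialch4.flux import (
    ReachScenario,
    attenuate,
    attenuation_table,
    diffusive_flux,
    excess_concentration,
    oxidation_vs_emission,
    residence_time_minutes,
)
from glacialch4.gas_physics import GasConditions, equilibrium_concentration
from glacialch4.gas_transfer import lake_transfer, river_transfer


class TestExcess:
    def test_saturated_water_has_zero_excess(self):
        assert excess_concentration(0.3, 0.3) == 0.0

    def test_river_excess_from_measured_concentration(self):
        ceq = equilibrium_concentration(GasConditions(1.0, atm_ch4_ppb=1900.0))
        assert round(excess_concentration(8.6 / 16.04, ceq.value), 2) == 0.53

    def test_undersaturation_is_negative(self):
        assert excess_concentration(0.0, 0.004) == pytest.approx(-0.004)


class TestDiffusiveFlux:
    def test_zero_excess_zero_flux(self):
        assert diffusive_flux(100.0, 0.0).flux_mmol_m2_d == 0.0

    def test_river_flux_digits(self):
        est = diffusive_flux(river_transfer(water_temp_c=1.0).kx_m_d, 0.53)
        assert round(est.flux_mmol_m2_d) == 63

    def test_lake_flux_digits(self):
        est = diffusive_flux(lake_transfer(water_temp_c=1.0).kx_m_d, 0.34)
        assert round(est.flux_mmol_m2_d, 2) == 0.05

    def test_umol_rendering_is_thousandfold(self):
        est = diffusive_flux(10.0, 0.5)
        assert est.flux_umol_m2_d == est.flux_mmol_m2_d * 1000.0

    @given(
        kx=st.floats(1e-3, 1e3),
        excess=st.floats(-10.0, 10.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_bilinear_in_k_and_excess(self, kx, excess, scale):
        base = diffusive_flux(kx, excess).flux_mmol_m2_d
        assert diffusive_flux(kx * scale, excess).flux_mmol_m2_d == pytest.approx(
            base * scale, rel=1e-9, abs=1e-12
        )
        assert diffusive_flux(kx, excess * scale).flux_mmol_m2_d == pytest.approx(
            base * scale, rel=1e-9, abs=1e-12
        )


class TestResidenceTime:
    @pytest.mark.parametrize(
        "discharge, minutes",
        [(50.0, 27), (10.0, 133)],
    )
    def test_seasonal_discharges(self, discharge, minutes):
        tau = residence_time_minutes(ReachScenario(discharge_m3_s=discharge))
        assert round(tau) == minutes

    def test_doubling_discharge_halves_residence(self):
        tau1 = residence_time_minutes(ReachScenario(discharge_m3_s=10.0))
        tau2 = residence_time_minutes(ReachScenario(discharge_m3_s=20.0))
        assert tau1 == pytest.approx(2 * tau2, rel=1e-12)

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            ReachScenario(depth_m=0.0)


class TestAttenuation:
    def test_zero_transit_removes_nothing(self):
        res = attenuate(0.53, 2.97, 0.0)
        assert res.removed_um == 0.0
        assert res.fraction_removed_pct == 0.0

    def test_summer_and_winter_scenarios(self):
        summer = attenuate(0.53, 2.97, 4000 / 2.5 / 60)
        winter = attenuate(0.53, 2.97, 4000 / 0.5 / 60)
        assert summer.removed_um == pytest.approx(0.055, abs=0.001)
        assert winter.removed_um == pytest.approx(0.275, abs=0.001)
        assert summer.fraction_removed_pct == pytest.approx(10.4, abs=0.1)
        assert winter.fraction_removed_pct == pytest.approx(51.9, abs=0.1)

    @given(
        c0=st.floats(1e-3, 100.0),
        rate=st.floats(0.0, 100.0),
        tau=st.floats(0.0, 1e5),
    )
    def test_mass_conservation_and_clamp(self, c0, rate, tau):
        res = attenuate(c0, rate, tau)
        assert res.removed_um + res.remaining_um == pytest.approx(c0, rel=1e-12)
        assert 0.0 <= res.removed_um <= c0
        assert 0.0 <= res.fraction_removed_pct <= 100.0

    def test_fraction_nondecreasing_in_tau_and_rate(self):
        taus = [0.0, 10.0, 100.0, 1000.0, 10000.0]
        fracs = [attenuate(0.5, 3.0, t).fraction_removed_pct for t in taus]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        rates = [0.0, 1.0, 3.0, 10.0]
        fracs = [attenuate(0.5, r, 100.0).fraction_removed_pct for r in rates]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_scenario_table_rounding_chain(self):
        """The rounded reporting chain (removed mass to 2 d.p. before the
        ratio) yields 11% and 53% at the seasonal discharges, where the
        exact fractions are 10.4% and 51.9%."""
        table = attenuation_table(
            0.53, 2.97,
            [ReachScenario(discharge_m3_s=q) for q in (50.0, 10.0)],
        )
        rounded = [round(v) for v in table["fraction_removed_rounded_pct"]]
        assert rounded == [11, 53]
        exact = table["fraction_removed_pct"].tolist()
        assert exact[0] == pytest.approx(10.38, abs=0.01)
        assert exact[1] == pytest.approx(51.89, abs=0.01)


class TestOxidationVsEmission:
    def test_equal_magnitudes(self):
        assert oxidation_vs_emission(63.0, 63.0, "umol/m2/d", "umol/m2/d") == 1.0

    def test_sediment_sink_exceeds_diffusive_source(self):
        ratio = oxidation_vs_emission(157.5, 63.0, "umol/m2/d", "umol/m2/d")
        assert ratio == pytest.approx(2.5, rel=1e-12)

    def test_mixed_scales_converted(self):
        ratio = oxidation_vs_emission(157.5, 0.063, "umol/m2/d", "mmol/m2/d")
        assert ratio == pytest.approx(2.5, rel=1e-12)

    def test_zero_oxidation(self):
        assert oxidation_vs_emission(0.0, 63.0, "umol/m2/d", "umol/m2/d") == 0.0

    def test_unit_must_be_explicit(self):
        with pytest.raises(ValueError, match="not recognized"):
            oxidation_vs_emission(157.5, 63.0, "umol", "umol/m2/d")
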