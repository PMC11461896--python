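"""Net rate estimation and per-area / per-mass re-expression."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from glacialch4.incubation import (
    IncubationAssay,
    net_rate,
    net_volumetric_rate,
    rates_frame,
    read_assay_table,
    sediment_surface_area,
    volumetric_to_areal,
    volumetric_to_mass_specific,
)
from glacialch4.synthetic import default_scenario, generate_incubation_dataset


def assay(initial, final, duration_h=21.0, **kwargs) -> IncubationAssay:
    return IncubationAssay(
        site_id="river",
        initial_um=tuple(initial),
        final_um=tuple(final),
        duration_h=duration_h,
        **kwargs,
    )


class TestVolumetricRate:
    def test_balanced_when_means_equal(self):
        a = assay([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert net_volumetric_rate(a) == 0.0
        assert net_rate(a).direction == "balanced"

    def test_strong_oxidation_magnitude(self):
        # (0.4 - 3.0) / (21/24) = -2.9714...: a river-like drawdown
        a = assay([3.0, 3.0, 3.0], [0.4, 0.4, 0.4], duration_h=21.0)
        rate = net_volumetric_rate(a)
        assert rate == pytest.approx(-2.6 / (21 / 24), rel=1e-12)
        assert round(rate, 2) == -2.97
        assert net_rate(a).direction == "net_oxidation"

    def test_weak_production(self):
        a = assay([1.0], [1.11], duration_h=22.0)
        assert net_volumetric_rate(a) == pytest.approx(0.12, abs=0.0005)
        assert net_rate(a).direction == "net_production"

    def test_replicate_order_invariance(self):
        a = assay([0.9, 1.0, 1.1], [0.5, 0.6, 0.4])
        b = assay([1.1, 0.9, 1.0], [0.4, 0.5, 0.6])
        assert net_volumetric_rate(a) == net_volumetric_rate(b)

    def test_unit_choice_commutes_with_estimation(self):
        """Converting concentrations to ug/L first and the rate back
        equals estimating in uM directly."""
        initial, final = [0.9, 1.0, 1.1], [0.5, 0.6, 0.4]
        in_um = net_volumetric_rate(assay(initial, final))
        in_ug = net_volumetric_rate(
            assay([16.04 * c for c in initial], [16.04 * c for c in final])
        )
        assert in_ug / 16.04 == pytest.approx(in_um, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"initial_um": (), "final_um": (1.0,)},
            {"initial_um": (1.0,), "final_um": ()},
            {"initial_um": (1.0,), "final_um": (1.0,), "duration_h": -1.0},
            {"initial_um": (-1.0,), "final_um": (1.0,)},
            {"initial_um": (1.0,), "final_um": (1.0,), "bulk_density_g_ml": 5.0},
        ],
    )
    def test_invalid_assays_rejected(self, kwargs):
        base = dict(site_id="x", initial_um=(1.0,), final_um=(1.0,),
                    duration_h=21.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            IncubationAssay(**base)


class TestGeometry:
    def test_standard_bottle_area(self):
        # 41 mm inner diameter -> 1320 mm^2 to 4 significant figures
        area = sediment_surface_area(41.0)
        assert float(f"{area:.4g}") == 1320.0

    @pytest.mark.parametrize(
        "diameter, expected",
        [(2.0, math.pi), (10.0, 78.5398)],
    )
    def test_circular_area(self, diameter, expected):
        assert sediment_surface_area(diameter) == pytest.approx(expected, rel=1e-4)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            sediment_surface_area(0.0)


class TestReExpression:
    def test_bottle_scale_areal_oxidation(self):
        area_m2 = sediment_surface_area(41.0) * 1e-6
        areal = volumetric_to_areal(2.97, 0.070, area_m2)
        assert areal == pytest.approx(157.47, abs=0.01)

    def test_identity_geometry(self):
        assert volumetric_to_areal(1.0, 1.0, 1.0) == 1.0
        assert volumetric_to_areal(0.0, 0.07, 1.3e-3) == 0.0

    def test_mass_specific(self):
        got = volumetric_to_mass_specific(2.97, 0.070, 5.0, 0.96)
        assert got == pytest.approx(2.97 * 0.07 / 4.8, rel=1e-12)

    def test_denser_sediment_gives_smaller_mass_rate(self):
        low = volumetric_to_mass_specific(2.97, 0.070, 5.0, 0.70)
        high = volumetric_to_mass_specific(2.97, 0.070, 5.0, 0.96)
        assert abs(high) < abs(low)

    @given(
        rate=st.floats(-10, 10, allow_nan=False),
        water_l=st.floats(0.01, 1.0),
        diameter=st.floats(5.0, 100.0),
        sed_ml=st.floats(1.0, 20.0),
        density=st.floats(0.2, 2.5),
    )
    def test_sign_and_ratio_structure(self, rate, water_l, diameter, sed_ml,
                                      density):
        """All three expressions share the sign, and areal/volumetric is
        exactly water_volume/area."""
        a = IncubationAssay(
            site_id="s",
            initial_um=(1.0,),
            final_um=(1.0,),
            duration_h=24.0,
            water_volume_l=water_l,
            sediment_volume_ml=sed_ml,
            bulk_density_g_ml=density,
            bottle_diameter_mm=diameter,
        )
        area_m2 = sediment_surface_area(diameter) * 1e-6
        areal = volumetric_to_areal(rate, water_l, area_m2)
        mass = volumetric_to_mass_specific(rate, water_l, sed_ml, density)
        for v in (areal, mass):
            assert math.copysign(1, v) == math.copysign(1, rate) or rate == 0
        if rate != 0:
            assert areal / rate == pytest.approx(water_l / area_m2, rel=1e-12)


class TestTableIO:
    def test_reader_recovers_generator_truth_at_zero_noise(self, tmp_path):
        scenario = default_scenario(seed=1, noise_sd_um=0.0)
        table = generate_incubation_dataset(scenario)
        path = tmp_path / "assays.csv"
        table.to_csv(path, index=False)
        frame = rates_frame(read_assay_table(path))
        by_site = frame.set_index("site_id")
        assert by_site.loc["river", "volumetric_um_l_d"] == pytest.approx(
            -2.97, rel=1e-9
        )
        assert by_site.loc["river", "direction"] == "net_oxidation"
        assert by_site.loc["lake", "volumetric_um_l_d"] == pytest.approx(
            0.12, rel=1e-9
        )
        assert by_site.loc["lake", "direction"] == "net_production"

    def test_inconsistent_geometry_rejected(self, tmp_path):
        table = generate_incubation_dataset(default_scenario(seed=1))
        table.loc[0, "duration_h"] = 99.0
        path = tmp_path / "assays.csv"
        table.to_csv(path, index=False)
        with pytest.raises(ValueError, match="inconsistent assay geometry"):
            read_assay_table(path)
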