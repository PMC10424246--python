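"""Dimensionless-number formulas, identities and impact classification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epidrop import printability as pr

spec_values = st.builds(
    pr.FluidJetSpec,
    viscosity=st.floats(1e-4, 1.0),
    surface_tension=st.floats(0.01, 0.1),
    density=st.floats(800.0, 1500.0),
    orifice_diameter=st.floats(1e-5, 1e-2),
    droplet_velocity=st.floats(0.01, 20.0),
)


class TestFormulas:
    def test_water_medium_reference_values(self, water_spec):
        # hand-evaluated: η/√(γρL), ρU²L/γ, ρUL/η, U/√(gL), ρgL²/γ, √(We·√Re)
        assert pr.ohnesorge(water_spec) == pytest.approx(0.0074199, rel=1e-4)
        assert 1.0 / pr.ohnesorge(water_spec) == pytest.approx(134.79, rel=1e-3)
        assert pr.weber(water_spec) == pytest.approx(13.7088, rel=1e-4)
        assert pr.reynolds(water_spec) == pytest.approx(499.0, rel=1e-4)
        assert pr.froude(water_spec) == pytest.approx(40.386, rel=1e-3)
        assert pr.bond(water_spec) == pytest.approx(0.008405, rel=1e-3)
        assert pr.splashing_parameter(water_spec) == pytest.approx(17.499, rel=1e-3)

    def test_ohnesorge_scaling(self, water_spec):
        doubled = pr.FluidJetSpec(
            viscosity=2 * water_spec.viscosity,
            surface_tension=water_spec.surface_tension,
            density=water_spec.density,
            orifice_diameter=water_spec.orifice_diameter,
        )
        assert pr.ohnesorge(doubled) == pytest.approx(
            2 * pr.ohnesorge(water_spec), rel=1e-12
        )
        quad_gamma = pr.FluidJetSpec(
            viscosity=water_spec.viscosity,
            surface_tension=4 * water_spec.surface_tension,
            density=water_spec.density,
            orifice_diameter=water_spec.orifice_diameter,
        )
        assert pr.ohnesorge(quad_gamma) == pytest.approx(
            0.5 * pr.ohnesorge(water_spec), rel=1e-12
        )

    def test_zero_velocity_numbers_vanish(self, water_spec):
        resting = pr.FluidJetSpec(
            viscosity=water_spec.viscosity,
            surface_tension=water_spec.surface_tension,
            density=water_spec.density,
            orifice_diameter=water_spec.orifice_diameter,
            droplet_velocity=0.0,
        )
        assert pr.weber(resting) == 0
        assert pr.reynolds(resting) == 0
        assert pr.froude(resting) == 0
        assert pr.splashing_parameter(resting) == 0
        prof = pr.profile(resting)
        assert not prof.splashing
        assert prof.oh == pytest.approx(pr.ohnesorge(water_spec))

    def test_bond_scales_quadratically_with_nozzle(self, water_spec):
        big = pr.FluidJetSpec(
            viscosity=water_spec.viscosity,
            surface_tension=water_spec.surface_tension,
            density=water_spec.density,
            orifice_diameter=10 * water_spec.orifice_diameter,
        )
        assert pr.bond(big) == pytest.approx(100 * pr.bond(water_spec), rel=1e-12)
        assert pr.bond(big) < 1  # 2.5 mm orifice still gravity-negligible

    @pytest.mark.parametrize(
        "field",
        ["viscosity", "surface_tension", "density", "orifice_diameter"],
    )
    def test_nonpositive_property_rejected(self, water_spec, field):
        kwargs = {
            "viscosity": water_spec.viscosity,
            "surface_tension": water_spec.surface_tension,
            "density": water_spec.density,
            "orifice_diameter": water_spec.orifice_diameter,
        }
        kwargs[field] = 0.0
        with pytest.raises(pr.InvalidSpecError):
            pr.FluidJetSpec(**kwargs)


class TestIdentities:
    @given(spec=spec_values)
    def test_ohnesorge_via_we_re_route(self, spec):
        direct = pr.ohnesorge(spec)
        via_we_re = math.sqrt(pr.weber(spec)) / pr.reynolds(spec)
        assert via_we_re == pytest.approx(direct, rel=1e-9)
        assert pr.profile(spec).z * direct == pytest.approx(1.0, rel=1e-12)

    @given(spec=spec_values)
    def test_profile_numbers_nonnegative(self, spec):
        prof = pr.profile(spec)
        for value in (prof.oh, prof.we, prof.re, prof.fr, prof.bo, prof.z,
                      prof.k_sp):
            assert value >= 0

    @given(spec=spec_values, factor=st.floats(1.1, 5.0))
    def test_splashing_parameter_monotone_in_velocity(self, spec, factor):
        faster = pr.FluidJetSpec(
            viscosity=spec.viscosity,
            surface_tension=spec.surface_tension,
            density=spec.density,
            orifice_diameter=spec.orifice_diameter,
            droplet_velocity=spec.droplet_velocity * factor,
        )
        assert pr.splashing_parameter(faster) > pr.splashing_parameter(spec)

    @given(spec=spec_values, u=st.floats(0.0, 20.0), eta=st.floats(1e-4, 1.0))
    def test_bond_independent_of_velocity_and_viscosity(self, spec, u, eta):
        other = pr.FluidJetSpec(
            viscosity=eta,
            surface_tension=spec.surface_tension,
            density=spec.density,
            orifice_diameter=spec.orifice_diameter,
            droplet_velocity=u,
        )
        assert pr.bond(other) == pytest.approx(pr.bond(spec), rel=1e-12)


class TestClassification:
    def test_boundary_epsilon(self, water_spec):
        # scale velocity so K_sp straddles 57.7 by ±1e-6
        def spec_with_ksp(target):
            from scipy.optimize import brentq

            def gap(u):
                s = pr.FluidJetSpec(
                    viscosity=water_spec.viscosity,
                    surface_tension=water_spec.surface_tension,
                    density=water_spec.density,
                    orifice_diameter=water_spec.orifice_diameter,
                    droplet_velocity=u,
                )
                return pr.splashing_parameter(s) - target

            u = brentq(gap, 0.1, 50.0, xtol=1e-12)
            return pr.FluidJetSpec(
                viscosity=water_spec.viscosity,
                surface_tension=water_spec.surface_tension,
                density=water_spec.density,
                orifice_diameter=water_spec.orifice_diameter,
                droplet_velocity=u,
            )

        eps = 1e-6
        below = pr.profile(spec_with_ksp(pr.SPLASHING_THRESHOLD - eps))
        above = pr.profile(spec_with_ksp(pr.SPLASHING_THRESHOLD + eps))
        assert not below.splashing
        assert above.splashing

    def test_gravity_flag_follows_bond(self, water_spec):
        assert pr.profile(water_spec).gravity_negligible
        heavy = pr.FluidJetSpec(
            viscosity=1.0,
            surface_tension=0.01,
            density=1500.0,
            orifice_diameter=5e-3,
        )
        assert pr.bond(heavy) > 1
        assert not pr.profile(heavy).gravity_negligible


class TestGravimetry:
    def test_reference_droplet_volume(self):
        cal = pr.GravimetricCalibration(
            total_mass=1.0e-5, droplet_count=1000, density=1000.0
        )
        volume, diameter = pr.droplet_volume(cal)
        assert volume == pytest.approx(1.0e-11)  # 10 nl
        assert diameter == pytest.approx(267.4e-6, rel=1e-3)

    def test_single_droplet_identity(self):
        cal = pr.GravimetricCalibration(
            total_mass=1000.0 * 5e-9, droplet_count=1, density=1000.0
        )
        assert pr.droplet_volume(cal)[0] == pytest.approx(5e-9)

    def test_zero_mass_rejected(self):
        with pytest.raises(pr.InvalidSpecError):
            pr.GravimetricCalibration(total_mass=0.0, droplet_count=10,
                                      density=1000.0)


class TestVelocity:
    def test_exact_linear_track(self):
        assert pr.droplet_velocity([0.0, 2e-3, 4e-3], 1e-3) == pytest.approx(2.0)

    def test_stationary(self):
        assert pr.droplet_velocity([1e-3] * 5, 1e-3) == pytest.approx(0.0)

    def test_noisy_track_recovers_slope(self, rng):
        t = np.arange(50) * 1e-3
        positions = 1.7 * t + rng.normal(0, 1e-5, t.size)
        est = pr.droplet_velocity(positions, 1e-3)
        assert est == pytest.approx(1.7, abs=0.05)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            pr.droplet_velocity([0.0], 1e-3)


class TestConfigLoading:
    def test_lab_units_roundtrip(self, tmp_path):
        path = tmp_path / "medium.yaml"
        path.write_text(
            "viscosity: 1.0 mPa.s\n"
            "surface_tension: 72.8 mN/m\n"
            "density: 0.998 g/ml\n"
            "orifice_diameter: 250 um\n"
            "droplet_velocity: 2.0 m/s\n"
        )
        spec = pr.load_fluid_spec(path)
        assert spec.viscosity == pytest.approx(1.0e-3)
        assert spec.surface_tension == pytest.approx(0.0728)
        assert spec.density == pytest.approx(998.0)
        assert spec.orifice_diameter == pytest.approx(250e-6)
        assert spec.droplet_velocity == pytest.approx(2.0)

    def test_bare_numbers_are_si(self):
        spec = pr.load_fluid_spec(
            {"viscosity": 1e-3, "surface_tension": 0.0728, "density": 998,
             "orifice_diameter": 250e-6}
        )
        assert spec.orifice_diameter == 250e-6

    def test_unknown_unit_rejected(self):
        with pytest.raises(pr.InvalidSpecError, match="unknown unit"):
            pr.load_fluid_spec(
                {"viscosity": "1.0 poise", "surface_tension": 0.07,
                 "density": 1000, "orifice_diameter": 250e-6}
            )

    def test_missing_field_rejected(self):
        with pytest.raises(pr.InvalidSpecError, match="missing"):
            pr.load_fluid_spec({"viscosity": 1e-3})
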