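"""Single-part solver: conduction, convection, evaporation, energy closure."""

import math

import pytest

from partitherm.anthropometry import size_part
from partitherm.environment import Environment, air_properties, saturation_vapour_pressure
from partitherm.part_balance import (
    InsulationLayer,
    PartState,
    conduction_resistance,
    convective_coefficient,
    evaporative_flux,
    solve_part,
    temperature_profile,
)


@pytest.fixture
def bare_cylinder():
    return size_part(25.0, 1050.0, "cylinder", 2.2, part_id="trunk", fat_fraction=0.15)


class TestConduction:
    def test_composite_cylinder_matches_analytic(self):
        """Two-layer radial conduction with fixed boundary temperatures
        equals Q = 2 pi L dT / sum(ln(r_out/r_in)/k)."""
        L, r0, r1, r2 = 0.6, 0.10, 0.12, 0.125
        k1, k2 = 0.5, 0.042
        dT = 10.0
        R = (conduction_resistance("cylinder", r0, r1, k1, L)
             + conduction_resistance("cylinder", r1, r2, k2, L))
        q = dT / R
        q_analytic = 2 * math.pi * L * dT / (math.log(r1 / r0) / k1 + math.log(r2 / r1) / k2)
        assert q == pytest.approx(q_analytic, rel=1e-6)

    def test_sphere_shell_formula(self):
        R = conduction_resistance("sphere", 0.05, 0.08, 0.2)
        assert R == pytest.approx((1 / 0.05 - 1 / 0.08) / (4 * math.pi * 0.2), rel=1e-12)

    def test_degenerate_shell_is_zero(self):
        assert conduction_resistance("cylinder", 0.1, 0.1, 0.5, 1.0) == 0.0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            conduction_resistance("cylinder", 0.2, 0.1, 0.5, 1.0)


class TestConvectiveCoefficient:
    def test_monotone_in_wind(self, bare_cylinder):
        env = lambda v: Environment(TA=20.0, VEL=v, RH=50.0)
        hs = [convective_coefficient(bare_cylinder, env(v), 30.0)
              for v in (0.0, 0.2, 0.5, 1.0, 2.0, 5.0)]
        assert all(b > a for a, b in zip(hs, hs[1:]))

    def test_still_air_equals_pure_free_convection(self, bare_cylinder):
        """At VEL = 0 the mixed correlation collapses onto free convection:
        halving a hypothetical forced contribution changes nothing."""
        env = Environment(TA=20.0, VEL=0.0, RH=50.0)
        h0 = convective_coefficient(bare_cylinder, env, 35.0)
        props = air_properties(27.5)
        D = bare_cylinder.characteristic_dimension
        gr = 9.80665 * 15.0 * D**3 / ((27.5 + 273.15) * props.kinematic_viscosity**2)
        ra = gr * props.prandtl
        nu_free = (0.60 + 0.387 * ra ** (1 / 6)
                   / (1 + (0.559 / props.prandtl) ** (9 / 16)) ** (8 / 27)) ** 2
        assert h0 == pytest.approx(nu_free * props.conductivity / D, rel=1e-9)

    def test_reynolds_number_hand_arithmetic(self, bare_cylinder):
        """Re = VEL*D/nu: direct arithmetic check for a 0.1 m cylinder at 1 m/s."""
        nu = 1.5e-5
        assert 1.0 * 0.1 / nu == pytest.approx(6666.7, rel=1e-3)
        # and the solver's own nu at 20 degC is within 10% of that textbook value
        assert air_properties(20.0).kinematic_viscosity == pytest.approx(1.5e-5, rel=0.1)


class TestEvaporativeFlux:
    def test_zero_at_saturation(self, bare_cylinder):
        env = Environment(TA=30.0, VEL=0.5, RH=100.0)
        assert evaporative_flux(30.0, 0.5, 0.5, 10.0, env) == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_wetness(self, bare_cylinder):
        env = Environment(TA=30.0, VEL=0.5, RH=20.0)
        f1 = evaporative_flux(35.0, 0.25, 0.5, 10.0, env)
        f2 = evaporative_flux(35.0, 0.50, 0.5, 10.0, env)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_psychrometric_oracle(self):
        """Independent humidity-ratio arithmetic at TA 30, RH 20, skin 35."""
        env = Environment(TA=30.0, VEL=1.0, RH=20.0)
        h, w, area = 12.0, 1.0, 1.0
        flux = evaporative_flux(35.0, w, area, h, env)
        # oracle: E = lambda * h/(cp Le^(2/3)) * (Mw/Ma) * (e_s - e_a)/P * A
        t_film = 32.5
        p = air_properties(t_film)
        lewis = p.thermal_diffusivity / p.diffusivity_water
        e_s = saturation_vapour_pressure(35.0)
        e_a = 0.2 * saturation_vapour_pressure(30.0)
        lam = 2.501e6 - 2361 * 35.0
        oracle = lam * h / (p.cp * lewis ** (2 / 3)) * (0.018015 / 0.0289647) \
            * (e_s - e_a) / 101325.0 * area
        assert flux == pytest.approx(oracle, rel=0.02)

    def test_wetness_out_of_range(self):
        env = Environment(TA=30.0, RH=50.0)
        with pytest.raises(ValueError):
            evaporative_flux(35.0, 1.5, 1.0, 10.0, env)


class TestSolvePart:
    def test_isothermal_equilibrium(self, bare_cylinder):
        """TA = radiant temps = core, saturated air, dry skin: no gradients,
        no generation."""
        env = Environment(TA=37.0, VEL=0.1, RH=100.0, T_sky=37.0, T_ground=37.0)
        state = PartState(T_core_target=37.0, pct_wet=0.0)
        sol = solve_part(bare_cylinder, state, env)
        assert sol.Q_gen == pytest.approx(0.0, abs=1e-4)
        assert sol.T_skin == pytest.approx(37.0, abs=0.01)
        assert sol.converged

    def test_newton_cooling_with_injected_coefficient(self, bare_cylinder):
        """With a prescribed skin temperature and injected h, convection is
        exactly Newtonian and radiation exactly Stefan-Boltzmann."""
        env = Environment(TA=20.0, VEL=0.5, RH=30.0)
        state = PartState(T_core_target=37.0, pct_wet=0.0)
        h = 7.5
        sol = solve_part(bare_cylinder, state, env, h_override=h, t_skin_override=33.0)
        assert sol.Q_conv == pytest.approx(
            h * bare_cylinder.area_skin * (33.0 - 20.0), rel=1e-9)
        sigma, eps = 5.670374419e-8, 0.98
        q_rad = eps * sigma * bare_cylinder.area_skin * ((33 + 273.15) ** 4 - (20 + 273.15) ** 4)
        assert sol.Q_rad == pytest.approx(q_rad, rel=1e-9)

    def test_energy_closure(self, bare_cylinder):
        env = Environment(TA=15.0, VEL=1.0, RH=40.0)
        sol = solve_part(bare_cylinder, PartState(), env)
        assert sol.converged
        assert abs(sol.residual) <= 0.01
        # the solution's own bookkeeping: Qgen - Qevap = Qins
        assert sol.Q_gen - sol.Q_evap_cut == pytest.approx(sol.Q_ins, abs=0.01)

    def test_hot_environment_reverses_flux_signs(self, bare_cylinder):
        """Hotter-than-body surroundings with dry skin: convection and
        radiation both become gains (negative losses)."""
        env = Environment(TA=45.0, VEL=0.5, RH=30.0, T_sky=45.0, T_ground=45.0)
        sol = solve_part(bare_cylinder, PartState(T_core_target=37.0, pct_wet=0.0), env)
        assert sol.Q_conv < 0 and sol.Q_rad < 0
        assert sol.Q_gen < 0  # net heat gain must be offset by negative generation

    def test_clothed_part_insulation_surface_between_skin_and_air(self, bare_cylinder):
        env = Environment(TA=0.0, VEL=1.0, RH=50.0)
        clo = InsulationLayer(depth=0.005, conductivity=0.042)
        sol = solve_part(bare_cylinder, PartState(dorsal=clo, ventral=clo), env)
        assert env.TA < sol.T_ins_dorsal < sol.T_skin

    def test_determinism(self, bare_cylinder):
        env = Environment(TA=10.0, VEL=0.7, RH=60.0)
        a = solve_part(bare_cylinder, PartState(), env)
        b = solve_part(bare_cylinder, PartState(), env)
        assert a.T_skin == b.T_skin and a.Q_gen == b.Q_gen


class TestTemperatureProfile:
    def test_flat_profile_when_isothermal(self, bare_cylinder):
        env = Environment(TA=37.0, VEL=0.1, RH=100.0, T_sky=37.0, T_ground=37.0)
        state = PartState(T_core_target=37.0, pct_wet=0.0)
        sol = solve_part(bare_cylinder, state, env)
        nodes = temperature_profile(bare_cylinder, state, sol)
        temps = [t for _, t in nodes]
        assert max(temps) - min(temps) < 0.02

    def test_cold_ordering_and_layer_fourier_law(self, bare_cylinder):
        env = Environment(TA=5.0, VEL=0.5, RH=50.0)
        clo = InsulationLayer(depth=0.004, conductivity=0.042)
        state = PartState(dorsal=clo, ventral=clo)
        sol = solve_part(bare_cylinder, state, env)
        nodes = dict(temperature_profile(bare_cylinder, state, sol))
        assert nodes["core"] > nodes["fat_boundary"] > nodes["skin"] > nodes["insulation_surface"]
        # flesh layer Fourier law: Qgen = dT / R_gen (re-derived here)
        from partitherm.part_balance import _core_to_skin_resistance
        R = _core_to_skin_resistance(bare_cylinder, state)
        assert (nodes["core"] - nodes["skin"]) / R == pytest.approx(sol.Q_gen, rel=1e-6)

    def test_unconverged_input_rejected(self, bare_cylinder):
        env = Environment(TA=5.0, VEL=0.5, RH=50.0)
        state = PartState()
        sol = solve_part(bare_cylinder, state, env, t_skin_override=30.0)
        with pytest.raises(ValueError):
            temperature_profile(bare_cylinder, state, sol)
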