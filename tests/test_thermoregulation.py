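"""Whole-body loop: aggregation, the effector cascade, vector runs."""

import numpy as np
import pytest

from partitherm.environment import Environment, latent_heat_vaporisation
from partitherm.part_balance import PartState
from partitherm.thermoregulation import (
    HumanSpec,
    SolveOptions,
    aggregate,
    initial_state,
    run_vector,
    solve_human,
)


class TestInitialState:
    def test_vasoconstricted_floor(self, default_human):
        states = initial_state(default_human)
        assert set(states) == {"head", "trunk", "arm", "leg"}
        for st in states.values():
            assert st.k_flesh == default_human.k_flesh_min
            assert st.fat_factor == 1.0
            assert st.pct_wet == default_human.pct_wet_baseline

    def test_part_specific_core_targets(self, default_human):
        states = initial_state(default_human)
        assert states["arm"].T_core_target == 35.0
        assert states["leg"].T_core_target == 36.7
        assert states["trunk"].T_core_target == 36.5

    def test_custom_mode_round_trips(self, default_human):
        custom = {pid: PartState(k_flesh=1.0) for pid in ("head", "trunk", "arm", "leg")}
        out = initial_state(default_human, mode="custom", custom=custom)
        assert out == custom

    def test_unknown_mode_rejected(self, default_human):
        with pytest.raises(ValueError):
            initial_state(default_human, mode="relaxed")


class TestAggregate:
    def _geoms(self, human):
        return {g.part_id: g for g in human.geometry()}

    def test_identical_parts_return_common_value(self, default_human, indoor_env):
        sol = solve_human(default_human, indoor_env)
        geoms = sol.geometries
        # overwrite every part with the trunk's solution: mean must equal it
        trunk = sol.parts["trunk"]
        from dataclasses import replace
        fake = {pid: replace(trunk, part_id=pid) for pid in geoms}
        agg = aggregate(fake, geoms)
        assert agg["T_skin"] == pytest.approx(trunk.T_skin, rel=1e-12)

    def test_weights_sum_to_one(self, default_human, indoor_env):
        sol = solve_human(default_human, indoor_env)
        agg = aggregate(sol.parts, sol.geometries)
        assert agg["weights_sum"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_weighted_mean(self, default_human, indoor_env):
        sol = solve_human(default_human, indoor_env)
        geoms = sol.geometries
        total = sum(g.count * g.area_skin for g in geoms.values())
        oracle = sum(g.count * g.area_skin * sol.parts[p].T_skin
                     for p, g in geoms.items()) / total
        assert sol.T_skin == pytest.approx(oracle, rel=1e-12)

    def test_limb_fluxes_doubled(self, default_human, indoor_env):
        sol = solve_human(default_human, indoor_env)
        by_hand = sum(sol.geometries[p].count * s.Q_gen for p, s in sol.parts.items())
        assert sol.Q_gen_net == pytest.approx(by_hand, rel=1e-12)


class TestSolveHuman:
    def test_indoor_reference_condition(self, default_human, indoor_env):
        """21 degC, 0.1 m/s, 50% RH, default lightly clothed human: core at
        its resting target and net generation at or above the minimum."""
        sol = solve_human(default_human, indoor_env)
        assert sol.status in ("thermoneutral", "cold_compensating")
        assert sol.T_core_trunk == pytest.approx(36.5)
        assert sol.Q_gen_net >= default_human.Q_min - 0.5
        assert abs(sol.balance_residual) <= 0.05

    def test_saturated_isothermal_limit_exhausts_cascade(self, default_human):
        """Air, radiant temps and humidity leave no gradient for any loss
        pathway: the cascade must raise core (Q10) or concede storage."""
        env = Environment(TA=37.0, VEL=0.1, RH=100.0, T_sky=37.0, T_ground=37.0)
        sol = solve_human(default_human, env,
                          SolveOptions(stop_at_core=43.5))
        assert sol.status in ("storage_implied", "regulating_heat", "max_iter")
        assert sol.T_core_trunk > 36.5  # core forced upward

    def test_cold_sweep_linear_in_air_temperature(self, nude_human):
        """Below the LCT the required net generation falls linearly with TA."""
        tas = np.arange(0.0, 19.0, 2.0)
        sols = run_vector(nude_human, tas, [0.1] * len(tas), [50.0] * len(tas))
        q = np.array([s.Q_gen_net for s in sols])
        assert all(s.status == "cold_compensating" for s in sols)
        r = np.corrcoef(tas, q)[0, 1]
        assert r ** 2 > 0.99
        slope = np.polyfit(tas, q, 1)[0]
        assert slope < 0

    def test_q10_law_exact(self, nude_human):
        """Whenever the core is elevated, Q_min_eff/Q_min = Q10^(dT/10) to
        machine precision."""
        env = Environment(TA=38.0, VEL=1.0, RH=60.0, T_sky=38.0, T_ground=38.0)
        sol = solve_human(nude_human, env)
        assert sol.T_core_trunk > 36.5
        expected = 2.0 ** ((sol.T_core_trunk - 36.5) / 10.0)
        assert sol.Q_min_effective / sol.Q_min == pytest.approx(expected, rel=1e-12)

    def test_sweat_accounting(self, nude_human):
        """Reported sweat = evaporative loss / (lambda * r), capped at max."""
        env = Environment(TA=40.0, VEL=1.0, RH=40.0, T_sky=40.0, T_ground=40.0)
        sol = solve_human(nude_human, env)
        r = 1.0 - sol.pct_wet ** 2 / 2.0
        lam = latent_heat_vaporisation(sol.T_skin)
        expected = sol.Q_evap_cut / (lam * r) * 3600.0
        assert sol.sweat_rate_L_h == pytest.approx(
            min(expected, nude_human.sweat_max), rel=1e-9)
        assert sol.sweat_rate_L_h <= nude_human.sweat_max + 1e-12
        assert sol.evaporation_efficiency == pytest.approx(r)

    def test_whole_body_closure(self, default_human):
        for ta, rh in ((5.0, 30.0), (21.0, 50.0), (33.0, 60.0)):
            sol = solve_human(default_human, Environment(TA=ta, VEL=0.5, RH=rh))
            assert abs(sol.balance_residual) <= 0.05

    def test_determinism_bit_identical(self, default_human, indoor_env):
        a = solve_human(default_human, indoor_env)
        b = solve_human(default_human, indoor_env)
        assert a.T_skin == b.T_skin
        assert a.Q_gen == b.Q_gen
        assert a.pct_wet == b.pct_wet

    def test_effector_cascade_ordering(self, default_human):
        """Rising TA at fixed RH: conductivity is non-decreasing while the
        skin stays below the control point, then the core target and skin
        wetness rise in turn."""
        tas = [24.0, 26.0, 28.0, 30.0, 32.0, 34.0]
        sols = run_vector(default_human, tas, [0.1] * 6, [50.0] * 6)
        below = [s for s in sols if s.T_skin < 35.0]
        ks = [s.k_flesh for s in below]
        assert all(b >= a - 1e-9 for a, b in zip(ks, ks[1:]))
        # the discrete cascade is path-dependent (the 10x wetness ramp above
        # 35 degC skin can balance a hotter cell at a marginally lower core),
        # so core ordering holds to within ~two core steps
        cores = [s.T_core_trunk for s in sols]
        assert all(b >= a - 0.25 for a, b in zip(cores, cores[1:]))
        wets = [s.pct_wet for s in sols]
        assert all(b >= a - 1e-9 for a, b in zip(wets, wets[1:]))

    def test_exceed_tcmax_off_concedes_storage(self):
        human = HumanSpec.nude(exceed_tcmax=False)
        env = Environment(TA=45.0, VEL=0.1, RH=90.0, T_sky=45.0, T_ground=45.0)
        sol = solve_human(human, env)
        assert sol.status in ("storage_implied", "max_iter")
        assert sol.T_core_trunk <= human.TC_MAX + 1e-9

    def test_maxiter_returns_last_state_not_exception(self):
        human = HumanSpec.nude(maxiter=3)
        env = Environment(TA=45.0, VEL=0.1, RH=90.0, T_sky=45.0, T_ground=45.0)
        sol = solve_human(human, env)
        assert sol.status in ("max_iter", "storage_implied")
        assert sol.iterations <= 3


class TestRunVector:
    def test_single_element_equals_direct_solve(self, default_human, indoor_env):
        direct = solve_human(default_human, indoor_env)
        vec = run_vector(default_human, [21.0], [0.1], [50.0])
        assert vec[0].Q_gen_net == direct.Q_gen_net
        assert vec[0].T_skin == direct.T_skin

    def test_length_mismatch_rejected(self, default_human):
        with pytest.raises(ValueError):
            run_vector(default_human, [0.0, 1.0], [0.1], [50.0])

    def test_statelessness_under_permutation(self, default_human):
        tas = [15.0, 25.0, 35.0]
        fwd = run_vector(default_human, tas, [0.1] * 3, [50.0] * 3)
        rev = run_vector(default_human, tas[::-1], [0.1] * 3, [50.0] * 3)
        for a, b in zip(fwd, rev[::-1]):
            assert a.Q_gen_net == b.Q_gen_net
            assert a.T_skin == b.T_skin
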