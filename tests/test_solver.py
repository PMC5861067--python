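"""Instantaneous network solve: valve branches, conservation, linearity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mozpump as mp
from mozpump.solver import _branch_solution, impedance_state, periodic_average

NL = 1e-12  # m^3/s per nL/s


class TestImpedanceState:
    def test_forward_branches(self, config):
        st_ = impedance_state(+1, +1, config)
        assert st_.k2 == pytest.approx(6.26e13, rel=1e-2)
        assert st_.k3 == pytest.approx(1.96e12, rel=1e-2)
        assert not st_.pharyngeal_valve_closed
        assert not st_.esophageal_valve_closed

    def test_pharyngeal_backflow_branch(self, config):
        st_ = impedance_state(-1, +1, config)
        assert st_.k2 == pytest.approx(3.97e15, rel=1e-2)
        assert st_.pharyngeal_valve_closed

    def test_esophageal_backflow_branch(self, config):
        fwd = impedance_state(+1, +1, config)
        back = impedance_state(+1, -1, config)
        assert back.k3 == pytest.approx(1e6 * fwd.k3)

    def test_zero_sign_is_forward(self, config):
        st_ = impedance_state(0, 0, config)
        assert not st_.pharyngeal_valve_closed
        assert not st_.esophageal_valve_closed


class TestSolveInstant:
    def test_static_system(self, config):
        sol = mp.solve_instant(0.0, 0.0, config)
        assert sol.q1_m3_s == sol.q2_m3_s == sol.q3_m3_s == 0.0
        assert sol.p_cp_pa == config.boundaries.p_food_pa
        assert sol.p_pp_pa == config.boundaries.p_food_pa

    def test_expanding_cp_draws_through_proboscis(self, config):
        """CP expansion closes both valves and pulls nearly all inflow up
        the feeding canal."""
        sol = mp.solve_instant(1 * NL, 0.0, config)
        assert sol.impedances.pharyngeal_valve_closed
        assert sol.impedances.esophageal_valve_closed
        assert sol.q1_m3_s == pytest.approx(0.9997 * NL, rel=1e-3)
        assert sol.q2_m3_s == pytest.approx(-2.5e-4 * NL, rel=0.05)
        assert sol.q3_m3_s == pytest.approx(sol.q2_m3_s, rel=1e-6)

    def test_cp_ejection_forward_branch(self, config):
        sol = mp.solve_instant(-1 * NL, 1 * NL, config)
        assert not sol.impedances.pharyngeal_valve_closed

    def test_pressure_flow_consistency(self, config):
        sol = mp.solve_instant(0.7 * NL, -0.3 * NL, config)
        k = sol.impedances
        p_food = config.boundaries.p_food_pa
        assert sol.p_cp_pa == pytest.approx(p_food - k.k1 * sol.q1_m3_s, rel=1e-12)
        assert sol.p_pp_pa == pytest.approx(
            sol.p_cp_pa - k.k2 * sol.q2_m3_s, rel=1e-12
        )

    @settings(deadline=None, derandomize=True)
    @given(
        vcp=st.floats(-20, 20),
        vpp=st.floats(-20, 20),
        dpg=st.floats(-1e3, 1e3),
    )
    def test_mass_conservation_any_input(self, vcp, vpp, dpg):
        """V-dot_CP = Q1 - Q2 and V-dot_PP = Q2 - Q3 on the accepted branch."""
        config = mp.default_config()
        sol = mp.solve_instant(vcp * NL, vpp * NL, config, dp_g_pa=dpg)
        scale = max(abs(sol.q1_m3_s), abs(sol.q3_m3_s), 1e-18)
        assert abs((sol.q1_m3_s - sol.q2_m3_s) - vcp * NL) < 1e-10 * scale
        assert abs((sol.q2_m3_s - sol.q3_m3_s) - vpp * NL) < 1e-10 * scale

    def test_frozen_impedance_superposition(self, config):
        """With impedances frozen to the forward branch the closed form is
        linear in (V-dot_CP, V-dot_PP, dp_g)."""
        k = impedance_state(+1, +1, config)
        args = (k.k1, k.k2, k.k3)
        a = np.array(_branch_solution(*args, 1 * NL, 0.0, 0.0, 0.0))
        b = np.array(_branch_solution(*args, 0.0, 2 * NL, 0.0, 0.0))
        c = np.array(_branch_solution(*args, 0.0, 0.0, 5.0, 0.0))
        combo = np.array(_branch_solution(*args, 1 * NL, 2 * NL, 5.0, 0.0))
        np.testing.assert_allclose(combo, a + b + c, rtol=1e-13, atol=1e-30)


class TestSimulateMode:
    def test_continuous_headline_numbers(self, continuous_result):
        assert periodic_average(continuous_result.q1_m3_s) == pytest.approx(
            0.58 * NL, rel=0.05
        )
        assert mp.max_proboscis_pressure_drop(continuous_result) == pytest.approx(
            760.0, rel=0.05
        )

    def test_burst_headline_numbers(self, burst_result):
        assert periodic_average(burst_result.q1_m3_s) == pytest.approx(
            16 * NL, rel=0.05
        )
        assert mp.max_proboscis_pressure_drop(burst_result) == pytest.approx(
            40e3, rel=0.05
        )

    @pytest.mark.parametrize("mode", ["continuous", "burst"])
    def test_time_averages_agree_across_tubes(self, config, mode):
        """Mass conservation: averaged Q1, Q2, Q3 identical over a cycle."""
        r = mp.simulate_mode(mode, config)
        q1 = periodic_average(r.q1_m3_s)
        for q in (r.q2_m3_s, r.q3_m3_s):
            assert periodic_average(q) == pytest.approx(q1, rel=5e-3)

    def test_per_step_mass_conservation(self, burst_result):
        r = burst_result
        scale = np.max(np.abs(r.q1_m3_s))
        assert np.max(np.abs(r.vdot_cp_m3_s - (r.q1_m3_s - r.q2_m3_s))) < 1e-10 * scale
        assert np.max(np.abs(r.vdot_pp_m3_s - (r.q2_m3_s - r.q3_m3_s))) < 1e-10 * scale

    def test_per_step_pressure_consistency(self, continuous_result, config):
        r = continuous_result
        k = mp.impedance_state(+1, +1, config)
        k2b = mp.impedance_state(-1, +1, config).k2
        k2 = np.where(r.pharyngeal_valve_closed, k2b, k.k2)
        np.testing.assert_allclose(
            r.p_cp_pa, config.boundaries.p_food_pa - k.k1 * r.q1_m3_s, rtol=1e-10
        )
        np.testing.assert_allclose(
            r.p_pp_pa, r.p_cp_pa - k2 * r.q2_m3_s, rtol=1e-10, atol=1e-12
        )

    @pytest.mark.parametrize("mode", ["continuous", "burst"])
    def test_grid_refinement_stability(self, config, mode):
        """Doubling the grid changes Q_gamma and dp_gamma by < 0.1%."""
        coarse = mp.simulate_mode(mode, config, n_steps=2000)
        fine = mp.simulate_mode(mode, config, n_steps=4000)
        q_c, q_f = (periodic_average(r.q1_m3_s) for r in (coarse, fine))
        dp_c, dp_f = (mp.max_proboscis_pressure_drop(r) for r in (coarse, fine))
        assert abs(q_f - q_c) / q_f < 1e-3
        assert abs(dp_f - dp_c) / dp_f < 1e-3

    def test_deterministic(self, config):
        a = mp.simulate_mode("burst", config, n_steps=500)
        b = mp.simulate_mode("burst", config, n_steps=500)
        np.testing.assert_array_equal(a.q1_m3_s, b.q1_m3_s)

    def test_empty_result_rejected(self, continuous_result):
        import dataclasses

        empty = dataclasses.replace(continuous_result, t_s=np.array([]))
        with pytest.raises(ValueError):
            mp.max_proboscis_pressure_drop(empty)
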