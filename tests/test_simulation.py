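"""Closed-loop assembly and time-domain integration."""

import numpy as np
import pytest

import ventcontrol as vc
from ventcontrol.simulation import _quadratic_node_flow


class TestSetpoint:
    def test_cycle_timing(self):
        pat = vc.BreathPattern(rate=15.0, ie_ratio=0.5, n_breaths=2)
        assert pat.t_total == pytest.approx(4.0)
        assert pat.t_insp == pytest.approx(4.0 / 3.0)
        t, p = vc.generate_setpoint(pat, dt=1e-3)
        assert abs(t.size - 2 * 4.0 / 1e-3) <= 1
        assert set(np.unique(p)) == {pat.peep, pat.p_insp}

    def test_ramp_shape_bounded_by_levels(self):
        pat = vc.BreathPattern(rise_time=0.3, n_breaths=1)
        t, p = vc.generate_setpoint(pat, dt=1e-3)
        assert p.min() >= pat.peep and p.max() <= pat.p_insp
        # mid-ramp value
        assert pat.setpoint(np.array([0.15]))[0] == pytest.approx(12.5)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            vc.BreathPattern(peep=10.0, p_insp=5.0)
        with pytest.raises(ValueError):
            vc.generate_setpoint(vc.BreathPattern(), dt=0.0)


class TestLureAssembly:
    def test_dimensions(self, plant, low_gain):
        lure = vc.assemble_lure(plant, low_gain)
        assert lure.n_states == 4
        assert lure.state_labels == ("x_b1", "x_b2", "p_lung", "x_c")

    def test_eigenvalues_match_closed_loop_poles(self, plant, low_gain):
        lure = vc.assemble_lure(plant, low_gain)
        tfs = vc.closed_loop_tfs(vc.ss_to_tf(plant).channel("p_aw"), low_gain)
        poles = np.sort_complex(np.roots(tfs["G_eu"].denominators[0]))
        eigs = np.sort_complex(np.linalg.eigvals(lure.A))
        assert np.allclose(eigs, poles, rtol=1e-6, atol=1e-9)

    def test_error_output_complements_pressure_step(self, plant, low_gain):
        # e = p_set - p_aw must hold sample-by-sample in a closed-loop run
        res = vc.simulate_linear(plant, low_gain, vc.BreathPattern(n_breaths=1))
        assert np.array_equal(res.e, res.p_set - res.p_aw)


class TestClosedLoopTFs:
    def test_toy_plant_algebra(self):
        # P_p = 1, C = k/s  ->  G_eu = k/(s+k)
        p = vc.RationalTF(((1.0,),), ((1.0,),), "p_control", ("p_aw",))
        tfs = vc.closed_loop_tfs(p, vc.IntegralController(2.0))
        g = tfs["G_eu"]
        w = np.logspace(-2, 2, 50)
        expected = 2.0 / (1j * w + 2.0)
        assert np.allclose(g.freq_response(w)[0], expected, rtol=1e-12)

    def test_integral_action_limits(self, g_eu, plant, low_gain):
        assert g_eu.evaluate(0j).real == pytest.approx(1.0, rel=1e-9)
        g_ep = vc.closed_loop_tfs(vc.ss_to_tf(plant).channel("p_aw"), low_gain)["G_ep"]
        assert abs(g_ep.evaluate(0j)) == pytest.approx(0.0, abs=1e-12)

    def test_requires_positive_gain(self, plant):
        with pytest.raises(ValueError):
            vc.closed_loop_tfs(vc.ss_to_tf(plant).channel("p_aw"), vc.IntegralController(0.0))


class TestLinearSimulation:
    def test_open_loop_misses_target_by_hose_drop(self, plant):
        """Feedforward alone leaves the leak-induced steady error."""
        pat = vc.BreathPattern(peep=0.0, p_insp=15.0, rate=4.0, ie_ratio=1.0, n_breaths=1)
        res = vc.simulate_linear(plant, vc.IntegralController(0.0), pat)
        i_end = int(pat.t_insp / res.dt) - 1
        assert res.p_aw[i_end] == pytest.approx(15.0 * 48.0 / 54.0, abs=1e-3)

    def test_integral_action_reaches_target(self, plant, low_gain):
        pat = vc.BreathPattern(peep=0.0, p_insp=15.0, rate=2.0, ie_ratio=1.0, n_breaths=1)
        res = vc.simulate_linear(plant, low_gain, pat)
        i_end = int(pat.t_insp / res.dt) - 1
        assert res.p_aw[i_end] == pytest.approx(15.0, abs=1e-2)

    def test_flow_conservation_identity(self, plant, low_gain, sweep_pattern):
        res = vc.simulate_linear(plant, low_gain, sweep_pattern)
        assert np.max(np.abs(res.q_out - res.q_pat - res.q_leak)) < 1e-9

    def test_compliance_relates_pressure_rate_to_flow(self, plant, low_gain, sweep_pattern, f1_params):
        res = vc.simulate_linear(plant, low_gain, sweep_pattern)
        dp = (res.p_lung[2:] - res.p_lung[:-2]) / (2 * res.dt)
        assert np.max(np.abs(f1_params.c_lung * dp - res.q_pat[1:-1])) < 0.02

    def test_step_refinement_convergence(self, plant, low_gain, sweep_pattern):
        a = vc.simulate_linear(plant, low_gain, sweep_pattern, dt=1e-3)
        b = vc.simulate_linear(plant, low_gain, sweep_pattern, dt=5e-4)
        rel = np.max(np.abs(a.states[-1] - b.states[-1])) / np.max(np.abs(b.states[-1]))
        assert rel < 1e-6

    def test_divergence_flagged_with_partial_trace(self, plant):
        # far beyond the discrete-time stability limit of the integrator
        res = vc.simulate_linear(plant, vc.IntegralController(1e4), vc.BreathPattern(n_breaths=2))
        assert res.status == "diverged"
        assert 0 < res.t.size < vc.BreathPattern(n_breaths=2).t_total / res.dt

    def test_equilibrium_is_stationary(self, plant, low_gain):
        xeq = vc.equilibrium_state(plant, low_gain, 5.0)
        # a nearly-constant set point holds the loop at the PEEP equilibrium
        const = vc.BreathPattern(peep=4.999999, p_insp=5.0, rate=60.0, ie_ratio=1e-9, n_breaths=1)
        res = vc.simulate_linear(plant, low_gain, const, x0=xeq)
        assert np.max(np.abs(res.p_aw - 5.0)) < 1e-6
        assert np.max(np.abs(res.q_pat)) < 1e-6


class TestSwitchedSimulation:
    def test_zero_alpha_reproduces_linear_run_bitwise(self, plant, low_gain, sweep_pattern):
        lin = vc.simulate_linear(plant, low_gain, sweep_pattern)
        nl = vc.SwitchNonlinearity.from_lmin(6.0, 0.0)
        res = vc.simulate_vgc(plant, low_gain, nl, sweep_pattern)
        assert np.array_equal(lin.states, res.states)
        assert np.array_equal(lin.p_aw, res.p_aw)

    def test_delta_above_peak_flow_reproduces_low_gain_bitwise(self, plant, low_gain, sweep_pattern):
        lin = vc.simulate_linear(plant, low_gain, sweep_pattern)
        peak_lmin = np.max(np.abs(lin.q_pat)) * 60.0
        nl = vc.SwitchNonlinearity.from_lmin(2.0 * peak_lmin, 18.5)
        res = vc.simulate_vgc(plant, low_gain, nl, sweep_pattern)
        assert np.array_equal(lin.states, res.states)
        assert not res.phi_active.any()

    def test_zero_delta_matches_frozen_high_gain_controller(self, plant, low_gain, sweep_pattern):
        alpha = 18.5
        frozen = vc.simulate_linear(
            plant, vc.IntegralController(low_gain.k_i * (1.0 + alpha)), sweep_pattern
        )
        res = vc.simulate_vgc(plant, low_gain, vc.SwitchNonlinearity(0.0, alpha), sweep_pattern)
        assert np.max(np.abs(frozen.p_aw - res.p_aw)) < 1e-9
        assert np.max(np.abs(frozen.q_pat - res.q_pat)) < 1e-9

    def test_switched_step_refinement_convergence(self, plant, low_gain, sweep_pattern):
        nl = vc.SwitchNonlinearity.from_lmin(6.0, 18.5)
        a = vc.simulate_vgc(plant, low_gain, nl, sweep_pattern, dt=1e-3)
        b = vc.simulate_vgc(plant, low_gain, nl, sweep_pattern, dt=5e-4)
        rel = np.max(np.abs(a.states[-1] - b.states[-1])) / np.max(np.abs(b.states[-1]))
        assert rel < 1e-6

    def test_switch_flag_tracks_flow_magnitude(self, plant, low_gain, sweep_pattern):
        nl = vc.SwitchNonlinearity.from_lmin(6.0, 18.5)
        res = vc.simulate_vgc(plant, low_gain, nl, sweep_pattern)
        active = res.phi_active.astype(bool)
        assert np.all(np.abs(res.q_pat[active]) * 60.0 > 6.0 - 1e-9)


class TestQuadraticLung:
    def test_node_flow_odd_and_zero_at_rest(self):
        for c, a_q in [(0.5, 3.0), (2.0, 0.7), (1e-6, 10.0)]:
            q = _quadratic_node_flow(c, a_q)
            assert _quadratic_node_flow(-c, a_q) == -q
            # solves the node balance a_q*Q|Q| + Q = c
            assert a_q * q * abs(q) + q == pytest.approx(c, rel=1e-12)
        assert _quadratic_node_flow(0.0, 1.0) == 0.0
        assert _quadratic_node_flow(0.3, 0.0) == 0.3

    def test_small_signal_matches_linear_lung(self, f1_params, blower_params, plant, low_gain):
        """Along a slow ramp the quadratic lung linearises to R = R_quad |Q*|."""
        pat = vc.BreathPattern(peep=5, p_insp=20, rate=10, ie_ratio=1.0, rise_time=2.9, n_breaths=1)
        q_star = f1_params.c_lung * (20.0 - 5.0) / 2.9  # compliance * ramp slope
        r_quad = f1_params.r_lung / q_star  # so R_quad*|Q*| equals the linear R_lung
        blower_ss = vc.build_blower_ss(blower_params)
        nl0 = vc.SwitchNonlinearity(0.0, 0.0)
        quad = vc.simulate_vgc_nonlinear_lung(
            f1_params, blower_ss, low_gain, nl0, pat, quadratic_r=r_quad
        )
        lin = vc.simulate_linear(plant, low_gain, pat)
        mid = slice(1500, 2800)  # mid-ramp, away from the corner transients
        assert np.max(np.abs(quad.p_aw[mid] - lin.p_aw[mid])) < 0.05
        assert np.max(np.abs(quad.q_pat[mid] - lin.q_pat[mid])) < 0.01

    def test_invalid_quadratic_resistance_rejected(self, f1_params, blower_params, low_gain):
        with pytest.raises(ValueError):
            vc.simulate_vgc_nonlinear_lung(
                f1_params, vc.build_blower_ss(blower_params), low_gain,
                vc.SwitchNonlinearity(0.0, 0.0), vc.BreathPattern(), quadratic_r=-1.0,
            )


class TestSimResultIO:
    def test_csv_round_trip_with_sidecar(self, plant, low_gain, tmp_path):
        import pandas as pd

        res = vc.simulate_linear(plant, low_gain, vc.BreathPattern(n_breaths=1))
        path = tmp_path / "trace.csv"
        res.write_csv(path)
        df = pd.read_csv(path)
        assert "p_aw [mbar]" in df.columns
        assert len(df) == res.t.size
        assert (tmp_path / "trace.json").exists()
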