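"""Performance-indicator computations on pressure/flow traces."""

import math

import numpy as np
import pytest

import ventcontrol as vc
from conftest import make_trace


def first_order_trace(tau=0.2, peep=0.0, delta=15.0, t_end=3.0, dt=1e-3, t0=0.0):
    t = np.arange(0.0, t_end, dt)
    p = peep + delta * (1.0 - np.exp(-np.maximum(t - t0, 0.0) / tau))
    return make_trace(t, p)


class TestRiseTime:
    def test_first_order_closed_form(self):
        # 10->90% crossing of a first-order rise: tau * ln 9
        trace = first_order_trace(tau=0.2)
        rt = vc.rise_time_10_90(trace, (0.0, 3.0), levels=(0.0, 15.0))
        assert rt == pytest.approx(0.2 * math.log(9.0), abs=1e-4)

    def test_instantaneous_step_is_zero_to_sampling_resolution(self):
        t = np.arange(0.0, 1.0, 1e-3)
        p = np.where(t >= 0.1, 15.0, 0.0)
        rt = vc.rise_time_10_90(make_trace(t, p), (0.0, 1.0), levels=(0.0, 15.0))
        assert 0.0 <= rt < 1e-3  # both crossings inside one sample interval

    def test_translation_invariance(self):
        a = vc.rise_time_10_90(first_order_trace(), (0.0, 3.0), levels=(0.0, 15.0))
        b = vc.rise_time_10_90(first_order_trace(t0=0.5, t_end=3.5), (0.5, 3.5), levels=(0.0, 15.0))
        assert a == pytest.approx(b, abs=1e-4)

    def test_unreached_level_is_nan(self):
        trace = first_order_trace(tau=5.0, t_end=1.0)
        assert math.isnan(vc.rise_time_10_90(trace, (0.0, 1.0), levels=(0.0, 15.0)))


class TestPlateau:
    @pytest.mark.parametrize("end_value,expected", [(14.9, 0.1), (12.5, 2.5), (15.0, 0.0)])
    def test_constant_tail(self, end_value, expected):
        t = np.arange(0.0, 2.0, 1e-3)
        p = np.full_like(t, end_value)
        err = vc.plateau_error(make_trace(t, p), (0.0, 2.0), target=15.0)
        assert err == pytest.approx(expected, abs=1e-9)


class TestFlowOvershoot:
    def test_monotone_decay_has_no_overshoot(self):
        t = np.arange(0.0, 3.0, 1e-3)
        q = -1.5 * np.exp(-t)
        assert vc.flow_overshoot(make_trace(t, np.zeros_like(t), q), (0.0, 3.0)) == 0.0

    @pytest.mark.parametrize("peak_ls,expected_lmin", [(0.025, 1.5), (0.04, 2.4)])
    def test_rebound_after_expiratory_peak(self, peak_ls, expected_lmin):
        t = np.arange(0.0, 4.0, 1e-3)
        q = np.zeros_like(t)
        q[500] = -1.5  # peak expiratory flow
        q[2000] = peak_ls  # later positive rebound
        q[300] = 2.0  # positive excursion before the peak must be ignored
        over = vc.flow_overshoot(make_trace(t, np.zeros_like(t), q), (0.2, 4.0))
        assert over == pytest.approx(expected_lmin, rel=1e-9)


class TestEvaluateSpecs:
    def test_perfect_tracking_passes_everything(self):
        pat = vc.BreathPattern(n_breaths=2)
        t = np.arange(0.0, 2 * pat.t_total + 1e-3, 1e-3)
        p = pat.setpoint(t)
        rep = vc.evaluate_specs(make_trace(t, p, pattern=pat))
        assert rep.pass_rise and rep.pass_plateau and rep.pass_overshoot
        assert rep.rise_time == 0.0 and rep.plateau_error == 0.0 and rep.flow_overshoot == 0.0

    def test_open_loop_fails_plateau_by_hose_drop(self, plant):
        """Without feedback the 20 mbar target misses by (1-8/9)*20 ~ 2.2 mbar."""
        pat = vc.BreathPattern(peep=5.0, p_insp=20.0, rate=10.0, ie_ratio=0.5, n_breaths=2)
        res = vc.simulate_linear(plant, vc.IntegralController(0.0), pat)
        rep = vc.evaluate_specs(res)
        assert not rep.pass_plateau
        assert rep.plateau_error == pytest.approx((1.0 - 48.0 / 54.0) * 20.0, abs=0.05)

    def test_thresholds_flip_only_their_own_flag(self):
        pat = vc.BreathPattern(n_breaths=1)
        t = np.arange(0.0, pat.t_total + 1e-3, 1e-3)
        p = pat.setpoint(t)
        q = np.zeros_like(t)
        q[int(pat.t_insp / 1e-3) + 200] = 0.05  # 3 L/min rebound during expiration
        q[int(pat.t_insp / 1e-3) + 100] = -1.0
        trace = make_trace(t, p, q, pattern=pat)
        strict = vc.evaluate_specs(trace, vc.SpecThresholds(overshoot_lmin=2.0))
        loose = vc.evaluate_specs(trace, vc.SpecThresholds(overshoot_lmin=4.0))
        assert not strict.pass_overshoot and loose.pass_overshoot
        assert strict.pass_rise == loose.pass_rise
        assert strict.pass_plateau == loose.pass_plateau

    def test_worst_case_aggregation_across_breaths(self):
        pat = vc.BreathPattern(n_breaths=2)
        t = np.arange(0.0, 2 * pat.t_total + 1e-3, 1e-3)
        p = pat.setpoint(t).astype(float)
        # second plateau misses the target by 3 mbar
        second = (t >= pat.t_total) & (np.mod(t, pat.t_total) < pat.t_insp)
        p[second] = pat.p_insp - 3.0
        rep = vc.evaluate_specs(make_trace(t, p, pattern=pat))
        assert rep.plateau_error == pytest.approx(3.0, abs=1e-6)
        assert not rep.pass_plateau
        assert len(rep.per_breath) == 2


class TestTradeoffDirections:
    def test_rise_falls_and_overshoot_grows_with_gain(self, plant, sweep_pattern):
        """The linear high-gain/low-gain tradeoff on the nominal plant."""
        table = vc.ki_sweep(plant, [0.4, 2.0, 10.0], sweep_pattern)
        rise = table["rise_time_s"].to_numpy()
        over = table["flow_overshoot_lmin"].to_numpy()
        assert np.all(np.diff(rise) < 0)
        assert np.all(np.diff(over) > 0)

    def test_switching_length_slows_rise_and_tempers_high_gain_overshoot(
        self, plant, low_gain, sweep_pattern
    ):
        """Any positive switching length cuts the high-gain flow overshoot."""
        table = vc.delta_sweep(plant, low_gain, 18.5, [0.0, 6.0, 40.0], sweep_pattern)
        rise = table["rise_time_s"].to_numpy()
        over = table["flow_overshoot_lmin"].to_numpy()
        assert np.all(np.diff(rise) >= -1e-9)
        assert over[1] < over[0] and over[2] < over[0]
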