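"""The linear controller's tradeoff: pressure rise time vs flow overshoot.

Sweeping the integral gain k_i over the clinically interesting range shows
that no single linear gain gives both a fast pressure build-up (rise time
near 0.2 s) and a quiet expiratory flow (overshoot under the 2 L/min
trigger threshold).
"""

import ventcontrol as vc

scenario = vc.nominal_scenario()
plant = scenario.plant()

table = vc.ki_sweep(plant, [0.4, 2.0, 10.0])
print(table[["k_i", "rise_time_s", "plateau_error_mbar", "flow_overshoot_lmin",
             "pass_rise", "pass_overshoot"]].to_string(index=False))
print()
print("Rise time falls with k_i while the flow overshoot grows: the low-gain")
print("controller is quiet but slow, the high-gain one fast but would falsely")
print("trigger an assisted breath (overshoot above 2 L/min).")
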