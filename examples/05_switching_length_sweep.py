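"""Influence of the switching length delta on performance.

delta = 0 freezes the high-gain controller; a delta above the peak patient
flow freezes the low-gain one.  In between, the rise time degrades
gracefully while the large high-gain flow overshoot is cut immediately.
"""

import ventcontrol as vc

scenario = vc.nominal_scenario()
plant = scenario.plant()

table = vc.delta_sweep(
    plant, scenario.controller, alpha=scenario.nonlinearity.alpha,
    delta_values_lmin=[0.0, 2.0, 6.0, 10.0, 20.0, 40.0, 80.0],
)
print(table[["delta_lmin", "rise_time_s", "flow_overshoot_lmin",
             "pass_rise", "pass_overshoot"]].to_string(index=False))
print()
print("Any delta in roughly 2-20 L/min keeps the rise time near the high-gain")
print("value and the overshoot well under the 2 L/min trigger threshold; the")
print("small residual overshoot at mid delta is the slow low-gain recovery of")
print("the release undershoot, not an oscillatory rebound.")
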