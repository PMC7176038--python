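# Nominal simulation parameter preset.
# Units are stated per field and converted to canonical units
# (mbar, L, s, L/s, L/mbar, mbar·s/L) at load time.
patient:
  r_lung: 5.0        # mbar·s/L
  c_lung_ml_per_mbar: 20.0   # mL/mbar
  r_hose: 6.0        # mbar·s/L
  r_leak: 48.0       # mbar·s/L
blower:
  f_n_hz: 30.0       # natural frequency, Hz
  zeta: 1.0          # damping ratio
controller:
  k_i: 0.4           # 1/s
  alpha: 18.5        # additional gain, dimensionless
  delta_lmin: 6.0    # switching length, L/min
pattern:
  peep: 5.0          # mbar
  p_insp: 20.0       # mbar
  rate: 15.0         # breaths/min
  ie_ratio: 0.5      # inspiration:expiration
  rise_time: 0.0     # s (0 = ideal step)
  n_breaths: 3
specs:
  rise_time_s: 0.2
  plateau_mbar: 2.0
  overshoot_lmin: 2.0
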