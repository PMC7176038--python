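# Methods

## Model

The respiratory circuit is a lumped one-compartment model.  Flows obey
conservation at the airway node, `Q_out = Q_pat + Q_leak`, with linear
resistive laws across the hose (`R_hose`), the intentional leak (`R_leak`)
and the lung (`R_lung`), and a compliant lung,
`C_lung · dp_lung/dt = Q_pat`.  Eliminating the airway node gives a
one-state system with state `p_lung`, input `p_out` and outputs
`[p_aw, Q_pat]`; the airway pressure is the resistive-divider value

    p_aw = (p_lung/R_lung + p_out/R_hose) / (1/R_lung + 1/R_hose + 1/R_leak).

The blower from commanded pressure `p_control` to outlet pressure `p_out`
is a critically damped second-order low-pass with natural frequency
2π·30 rad/s — unit DC gain, strong roll-off above ~190 rad/s.  The series
coupling is the 3-state plant `P(s) = [P_p; P_Q]` used everywhere else.
Internal canonical units are mbar, L, s (so flows in L/s, compliance in
L/mbar, resistance in mbar·s/L); the config layer accepts the conventional
reporting units (mL/mbar for compliance, L/min for flows and switching
lengths, Hz for the blower) and converts at the boundary.  The shipped
nominal preset is R_lung = 5 mbar·s/L, C_lung = 20 mL/mbar,
R_hose = 6 mbar·s/L, R_leak = 48 mbar·s/L.

Two closed-form facts anchor the implementation and are asserted in tests:
`P_p(0) = R_leak/(R_leak+R_hose)` (the lung is full at equilibrium, only
the leak flow drops pressure along the hose) and `P_Q(0) = 0`.

## Controllers

The baseline law is a pure integrator `C(s) = k_i/s` acting on
`e = p_set − p_aw`, plus a unity set-point feedforward.  A proportional
term is deliberately absent: it would only reduce the roll-off above the
bandwidth.  The variable-gain element injects `φ(Q_pat)·e` upstream of the
integrator, with `φ = 0` for `|Q_pat| ≤ δ` and `φ = α` otherwise, i.e.

    p_control = p_set + C(s) · (1 + φ(Q_pat)) · e.

The boundary `|Q_pat| = δ` belongs to the low-gain branch; there is no
hysteresis or debounce (chattering is handled by the integrator, below).
With `δ = 0` the law degenerates to the frozen high-gain controller
`C(s)(1+α)`; with `δ` above the peak flow, to the low-gain one.  The
injection satisfies the sector `0 ≤ φ(e,Q)/e ≤ α` for every argument,
independently of `δ`.

## Stability analysis

Written as a Lur'e system (linear loop driven by `u = −φ·e`), the
disturbance channel sees the complementary sensitivity
`G_eu = P_p C/(1+P_p C)` and the set-point channel
`G_ep = (1−P_p)/(1+P_p C)`.  Sufficient conditions for input-to-state
stability: (a) `G_eu` Hurwitz, (b) `Re G_eu(jω) > −1/α` for all ω,
(c) `1 + α G_eu(∞) > 0`, plus the sector condition.  Since both `P_p` and
`C` are strictly proper, `G_eu(∞) = 0` and (c) holds trivially with value
exactly 1.

Condition (b) is a global minimisation over frequency.  It is solved by a
dense log-grid scan (2000 points per decade over [1e−3, 1e5] rad/s,
widened to 100× the fastest pole/zero if needed) followed by bounded
scalar minimisation between the bracketing grid points; the ω = 0 value
and the ω → ∞ feedthrough limit are included as candidates.  The scan is
verified in tests against a 10⁶-point brute-force grid and against the
analytic fixture `1/(s+1)²` (minimum −1/8 at ω = √3, hence admissible gain
exactly 8).  The largest admissible additional gain is
`α_max = −1/min Re G_eu` (infinite when the real part never goes
negative).  Over a patient family, the reported `α_max` is the minimum of
the per-member values.  Strictness tolerances: Hurwitz requires pole real
parts below −1e−9; condition (b) uses a 1e−12 slack on the strict
inequality.  No Lyapunov/LMI certificate is constructed — the
frequency-domain conditions are checked directly.

## Integrator

Fixed-step classical RK4 at dt = 1 ms, with the set point sampled and held
over each step.  For each frozen value of the switched gain the closed
loop is LTI, so the RK4 step is precomputed once per gain mode as a matrix
recursion `x⁺ = M·x + N·p_set` (M is the degree-4 Taylor polynomial of
`exp(dt·A)`); this makes runs bit-reproducible and cheap (a 200-breath run
is ~8 s).  The gain mode is decided once per step from the current
outputs.  When a step would carry `|Q_pat|` across δ, the crossing instant
is localised by 60 bisection iterations on the RK4 map inside the step and
the step is split there (up to 8 splits per step against chattering).
Without this, switching times are quantised to the grid — an O(dt) error
that dominates step-halving comparisons; with it, fourth-order convergence
is restored (measured halving difference ~3e−7 norm-relative on the
switched scenario) and the degenerate-switch limits hold exactly: α = 0
and δ-above-peak-flow runs are bit-identical to the linear simulation, and
δ = 0 matches the frozen high-gain run to ~5e−14 mbar.

Step-halving convergence is measured as the max-norm of the end-of-run
state difference over the max-norm of the state: per-component relative
error is ill-posed because the blower states pass near zero at the end of
expiration.  Convergence experiments use breath patterns whose phase edges
are commensurate with both sample grids; otherwise the held set-point edge
itself moves by O(dt) and the comparison measures input quantisation, not
integrator error.  A guard aborts any run whose state magnitude exceeds
1e6 canonical units and returns the partial trace with status "diverged"
(exercised in tests with a gain far beyond the discrete-time stability
limit).

Simulated traces reconstruct every physical channel (`p_out`, `p_aw`,
`p_lung`, `Q_pat`, `Q_leak`, `Q_out`, hose drop) from the states through
the airway-node algebra, so `Q_out = Q_pat + Q_leak` holds to machine
precision by construction and is asserted to 1e−9 in tests.

The switch reads the plant's true `Q_pat`; sensor dynamics and noise are
not modelled.

## Quadratic test lung

Mechanical test lungs often realise the resistance as a simple orifice,
`Δp = R_quad·Q|Q|` (units mbar·s²/L²).  The airway-node balance then
becomes a scalar quadratic in `Q_pat`, which is solved in closed form at
every integrator stage — no iterative solver, hence no non-convergence
path.  The law is odd and linearises to an equivalent resistance
`R_quad·|Q*|` at operating flow `Q*`; both properties are tested, the
latter along a slow set-point ramp where the flow is nearly constant
(agreement to ~0.01 mbar at a 15 mbar ramp).

## Performance metrics

Per breath, aggregated worst-case across breaths (the specifications are
safety-style bounds):

* **Rise time** — first crossings of the 10 % and 90 % levels of the
  inspiratory step (peep + 0.1Δ, peep + 0.9Δ), linearly interpolated
  between samples; NaN if the 90 % level is never reached.  Target ≈ 0.2 s.
* **Plateau error** — distance of the mean airway pressure over the final
  5 % of the inspiration from the inspiratory target (the averaging
  suppresses sampling noise).  Target ±2 mbar.
* **Flow overshoot** — the largest positive patient flow after the
  (negative) peak expiratory flow within the expiration window, in L/min;
  positive flow during expiration is what falsely triggers an assisted
  breath.  Target: below the clinician trigger threshold, default 2 L/min.
  No trigger detector is simulated; the threshold comparison is the proxy.

Thresholds live in the config `[specs]` section.

## Study conditions and scenario choices

The default breath pattern is PEEP 5 mbar, inspiratory target 20 mbar,
15 breaths/min, I:E = 0.5, ideal steps — a fixture choice, configurable.
Parameter sweeps use a slower pattern (10 breaths/min, I:E = 0.5, so 2 s of
inspiration): with the unity feedforward the low-gain loop reaches ~89 % of
the step almost immediately and crawls through the last fraction at the
integral bandwidth, putting its 10–90 % rise near 1.4 s — the inspiration
must contain it for the metric to be defined at every sweep point.

The patient bank emulates a wide range of patient–hose combinations by
log-uniform sampling of the four circuit parameters over one decade
centred on the nominal preset, deterministic under a seed.  This is a
fixture policy, not a physiological survey: real populations are not
log-uniform, mask leaks vary in time, and patients breathe spontaneously —
none of which is modelled.  Passing bank-wide tests therefore demonstrates
robustness of the *method* across plant variation, not clinical coverage.

## Known limitations

* The blower is linear and unsaturated; commanded pressures may go
  negative during aggressive release, which a real device would clip.
  This makes ideal-step releases more aggressive than hardware ones.
* One consequence, visible in the δ sweep: the high-gain release makes
  `p_aw` undershoot the PEEP by ~2–3 mbar, and after the down-switch the
  low-gain recovery re-inflates the lung at ~0.5–1.2 L/min.  Measured as
  "largest positive expiratory flow", this grows mildly with δ, so the
  flow overshoot is not monotone non-increasing across the whole 0–80 L/min
  δ range on the nominal linear-lung plant — only its envelope (large at
  δ = 0, small for any δ > 0, zero at δ above the peak flow) follows the
  expected tradeoff direction.
* Spontaneous breathing, trigger detection, time-varying mask leaks and
  multi-compartment lungs are out of scope.
* `α_max` values reported here are model-based; on hardware the same
  conditions would be checked against measured frequency responses, and
  the numbers differ.
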