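"""Closed-loop assembly and fixed-step time-domain simulation.

The loop structure is: unity feedforward of the set point plus integral
feedback on the airway-pressure error, with the optional flow-switched
error injection upstream of the integrator,

    p_control = p_set + C(s) · (e + φ(Q_pat)·e),   e = p_set − p_aw.

Written as a linear block with the static nonlinearity in feedback (a Lur'e
system), the disturbance channel u = −φ(Q_pat)·e sees the complementary
sensitivity G_eu = P_p·C/(1 + P_p·C), and the set-point channel sees
G_ep = (1 − P_p)/(1 + P_p·C).

Integration uses the classical RK4 one-step map at a fixed step (default
1 ms).  Because the right-hand side is linear for each frozen value of the
switched gain and the set point is held over a step, the RK4 step reduces to
a matrix recursion x⁺ = M·x + N·p_set with one (M, N) pair per gain mode;
the switch decision is taken from the current outputs once per step.  When a
step would carry the flow across the switching boundary |Q_pat| = δ, the
crossing instant is localised by bisection inside the step and the step is
split there, so the switching time is resolved to machine precision rather
than quantised to the sample grid; this preserves the fourth-order step-size
convergence of the smooth phases.  Runs are bit-reproducible, and the
degenerate-switch limits (α = 0, or δ above the peak flow) coincide bitwise
with the linear simulation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .controllers import IntegralController, SwitchNonlinearity, phi_gain
from .plant import LinearStateSpace, PatientHoseParams, RationalTF

#: states beyond this magnitude (canonical units) abort a run as divergent
OVERFLOW_GUARD = 1e6

DEFAULT_DT = 1e-3


@dataclass(frozen=True)
class BreathPattern:
    """Periodic ventilation set-point pattern.

    ``peep`` (mbar) is held during expiration, ``p_insp`` (mbar) during
    inspiration; ``rate`` is in breaths/min and ``ie_ratio`` the
    inspiration:expiration duration ratio.  ``rise_time`` = 0 gives ideal
    steps; a positive value ramps the set point linearly over that many
    seconds at each transition (both build-up and release).
    """

    peep: float = 5.0
    p_insp: float = 20.0
    rate: float = 15.0
    ie_ratio: float = 0.5
    rise_time: float = 0.0
    n_breaths: int = 3

    def __post_init__(self) -> None:
        if not (self.p_insp > self.peep >= 0):
            raise ValueError("need p_insp > peep >= 0")
        if not (self.rate > 0 and self.ie_ratio > 0):
            raise ValueError("rate and ie_ratio must be positive")
        if not (self.rise_time >= 0 and self.n_breaths >= 1):
            raise ValueError("rise_time must be >= 0 and n_breaths >= 1")

    @property
    def t_total(self) -> float:
        return 60.0 / self.rate

    @property
    def t_insp(self) -> float:
        return self.t_total * self.ie_ratio / (1.0 + self.ie_ratio)

    @property
    def t_exp(self) -> float:
        return self.t_total - self.t_insp

    def setpoint(self, t: np.ndarray) -> np.ndarray:
        """Set-point values at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        phase = np.mod(t, self.t_total)
        delta = self.p_insp - self.peep
        if self.rise_time == 0.0:
            return np.where(phase < self.t_insp, self.p_insp, self.peep)
        r = self.rise_time
        up = self.peep + delta * np.clip(phase / r, 0.0, 1.0)
        down = self.p_insp - delta * np.clip((phase - self.t_insp) / r, 0.0, 1.0)
        return np.where(phase < self.t_insp, up, down)


def generate_setpoint(pattern: BreathPattern, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled set-point trace over ``n_breaths`` cycles.

    Returns ``(t, p_set)`` with t = 0, dt, …, n_breaths·T (inclusive).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    n = int(round(pattern.n_breaths * pattern.t_total / dt))
    t = np.arange(n + 1) * dt
    return t, pattern.setpoint(t)


@dataclass(frozen=True)
class LureSystem:
    """Closed loop written as linear dynamics plus a feedback nonlinearity.

    States ``[plant states…, x_c]`` where ``x_c`` integrates the (possibly
    augmented) error.  Inputs: the set point ``p_set`` and the nonlinearity
    channel ``u = −φ(Q_pat)·e``; outputs ``[e, Q_pat]``.  With u ≡ 0 this is
    exactly the linear low-gain closed loop.
    """

    A: np.ndarray
    B: np.ndarray
    B_u: np.ndarray
    C: np.ndarray
    D: np.ndarray
    state_labels: tuple[str, ...]
    output_labels: tuple[str, ...] = ("e", "Q_pat")
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def n_states(self) -> int:
        return self.A.shape[0]


def assemble_lure(plant: LinearStateSpace, ctrl: IntegralController) -> LureSystem:
    """Close the loop around the coupled plant with the integral controller.

    ``plant`` must expose outputs ``p_aw`` and ``Q_pat`` and be driven by
    ``p_control``.  The returned system appends the integrator state x_c with
    dynamics ẋ_c = e − u and feeds p_control = p_set + k_i·x_c (unity
    set-point feedforward included).
    """
    if plant.input_labels != ("p_control",):
        raise ValueError(f"plant must have input p_control, got {plant.input_labels}")
    try:
        i_paw = plant.output_index("p_aw")
        i_q = plant.output_index("Q_pat")
    except ValueError as exc:
        raise ValueError("plant must output p_aw and Q_pat") from exc
    if np.any(plant.D != 0.0):
        raise ValueError("coupled plant must be strictly proper")
    n = plant.n_states
    c_paw = plant.C[i_paw]
    c_q = plant.C[i_q]
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = plant.A
    A[:n, n] = plant.B[:, 0] * ctrl.k_i
    A[n, :n] = -c_paw  # ẋ_c = e = p_set − p_aw (u enters via B_u)
    B = np.zeros(n + 1)
    B[:n] = plant.B[:, 0]
    B[n] = 1.0
    B_u = np.zeros(n + 1)
    B_u[n] = -1.0  # u = −φe, so ẋ_c = e − u = e + φe
    C = np.zeros((2, n + 1))
    C[0, :n] = -c_paw
    C[1, :n] = c_q
    D = np.array([[1.0], [0.0]])
    return LureSystem(
        A=A,
        B=B,
        B_u=B_u,
        C=C,
        D=D,
        state_labels=plant.state_labels + ("x_c",),
        meta={**plant.meta, "k_i": ctrl.k_i},
    )


def closed_loop_tfs(plant_p: RationalTF, ctrl: IntegralController) -> dict[str, RationalTF]:
    """Closed-loop transfer functions of the Lur'e form.

    ``G_eu`` = P_p·C/(1+P_p·C) (complementary sensitivity, the path seen by
    the nonlinearity channel) and ``G_ep`` = (1−P_p)/(1+P_p·C) (set point to
    error).  ``plant_p`` must be the single pressure channel of the plant.
    """
    if ctrl.k_i <= 0:
        raise ValueError("closed_loop_tfs requires k_i > 0")
    if plant_p.n_channels != 1:
        plant_p = plant_p.channel("p_aw")
    n_p = np.asarray(plant_p.numerators[0])
    d_p = np.asarray(plant_p.denominators[0])
    k = ctrl.k_i
    den = np.polyadd(np.polymul((1.0, 0.0), d_p), k * n_p)  # s·d_p + k·n_p
    g_eu = RationalTF((tuple(k * n_p),), (tuple(den),), "u", ("e",))
    num_ep = np.polymul((1.0, 0.0), np.polysub(d_p, n_p))  # s·(d_p − n_p)
    g_ep = RationalTF((tuple(num_ep),), (tuple(den),), "p_set", ("e",))
    return {"G_eu": g_eu, "G_ep": g_ep}


@dataclass
class SimResult:
    """Uniformly sampled closed-loop traces in canonical units.

    ``status`` is "ok" or "diverged" (overflow guard hit; arrays truncated
    at the last finite sample).  ``u`` is the Lur'e disturbance −φ·e and
    ``phi_active`` flags samples where the high gain was engaged.
    """

    t: np.ndarray
    p_set: np.ndarray
    p_control: np.ndarray
    p_out: np.ndarray
    p_aw: np.ndarray
    p_lung: np.ndarray
    q_pat: np.ndarray
    q_leak: np.ndarray
    q_out: np.ndarray
    e: np.ndarray
    u: np.ndarray
    phi_active: np.ndarray
    delta_p: np.ndarray
    states: np.ndarray
    dt: float
    pattern: Optional[BreathPattern] = None
    status: str = "ok"
    meta: dict = field(default_factory=dict)

    _UNITS = {
        "t": "s", "p_set": "mbar", "p_control": "mbar", "p_out": "mbar",
        "p_aw": "mbar", "p_lung": "mbar", "q_pat": "L/s", "q_leak": "L/s",
        "q_out": "L/s", "e": "mbar", "u": "mbar", "phi_active": "0/1",
        "delta_p": "mbar",
    }

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"{name} [{unit}]": getattr(self, name) for name, unit in self._UNITS.items()}
        return pd.DataFrame(cols)

    def write_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write traces as CSV (unit-annotated header) plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {
                "dt": self.dt,
                "status": self.status,
                "pattern": None if self.pattern is None else vars(self.pattern).copy(),
                **{k: v for k, v in self.meta.items() if isinstance(v, (int, float, str, bool))},
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _rk4_powers(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, ...]:
    """Matrix powers reused when building the RK4 one-step map for any step length."""
    eye = np.eye(A.shape[0])
    A2 = A @ A
    return eye, A, A2, A2 @ A, A2 @ A2, b


def _rk4_step_matrices(powers: tuple[np.ndarray, ...], h: float) -> tuple[np.ndarray, np.ndarray]:
    """One-step RK4 map for ẋ = A x + b·p with p held over the step.

    Returns (M, N) with x⁺ = M x + N·p: M is the degree-4 Taylor polynomial
    of exp(h·A) and N its integral applied to b.
    """
    eye, A, A2, A3, A4, b = powers
    M = eye + h * A + h**2 / 2 * A2 + h**3 / 6 * A3 + h**4 / 24 * A4
    N = (h * eye + h**2 / 2 * A + h**3 / 6 * A2 + h**4 / 24 * A3) @ b
    return M, N


def _reconstruct(
    lure: LureSystem,
    t: np.ndarray,
    pset: np.ndarray,
    X: np.ndarray,
    phi_active: np.ndarray,
    alpha: float,
    dt: float,
    pattern: Optional[BreathPattern],
    status: str,
) -> SimResult:
    pp: PatientHoseParams = lure.meta["patient"]
    blower = lure.meta["blower"]
    k_i = lure.meta["k_i"]
    gl, gh, gk = 1.0 / pp.r_lung, 1.0 / pp.r_hose, 1.0 / pp.r_leak
    s_tot = gl + gh + gk
    p_out = blower.omega_n**2 * X[:, 1]
    p_lung = X[:, 2]
    x_c = X[:, 3]
    p_control = pset + k_i * x_c
    p_aw = (p_lung * gl + p_out * gh) / s_tot
    q_pat = (p_aw - p_lung) * gl
    q_leak = p_aw * gk
    q_out = (p_out - p_aw) * gh
    e = pset - p_aw
    u = -np.where(phi_active, alpha, 0.0) * e
    return SimResult(
        t=t, p_set=pset, p_control=p_control, p_out=p_out, p_aw=p_aw,
        p_lung=p_lung, q_pat=q_pat, q_leak=q_leak, q_out=q_out, e=e, u=u,
        phi_active=phi_active.astype(np.uint8), delta_p=p_out - p_aw, states=X,
        dt=dt, pattern=pattern, status=status, meta=dict(lure.meta),
    )


def _simulate_switched(
    plant: LinearStateSpace,
    ctrl: IntegralController,
    nl: SwitchNonlinearity,
    pattern: BreathPattern,
    dt: float,
    x0: Optional[np.ndarray],
) -> SimResult:
    if not dt > 0:
        raise ValueError("dt must be positive")
    lure = assemble_lure(plant, ctrl)
    n = lure.n_states
    t, pset = generate_setpoint(pattern, dt)
    nsamp = t.size
    c_q = lure.C[1, :].copy()
    # Gain-mode matrices: φ scales the error injection into x_c only.
    A_hi = lure.A.copy()
    A_hi[n - 1, :] *= 1.0 + nl.alpha
    b_hi = lure.B.copy()
    b_hi[n - 1] *= 1.0 + nl.alpha
    powers = (_rk4_powers(lure.A, lure.B), _rk4_powers(A_hi, b_hi))
    step_mats = (_rk4_step_matrices(powers[0], dt), _rk4_step_matrices(powers[1], dt))
    # With α = 0 the nonlinearity is identically zero: no switching to track.
    events = nl.alpha > 0.0 and math.isfinite(nl.delta)
    delta = nl.delta if events else math.inf
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    X = np.empty((nsamp, n))
    phi_active = np.zeros(nsamp, dtype=bool)
    status = "ok"
    end = nsamp
    for k in range(nsamp):
        X[k] = x
        if not np.all(np.abs(x) < OVERFLOW_GUARD):
            status = "diverged"
            end = k + 1
            break
        hi = bool(abs(c_q @ x) > delta)
        phi_active[k] = hi
        p = pset[k]
        remaining = dt
        # Advance one sample, splitting the step at |Q_pat| = δ crossings so
        # switching instants are resolved below the sample grid.
        for _ in range(8):
            M, N = step_mats[hi] if remaining == dt else _rk4_step_matrices(powers[hi], remaining)
            x_cand = M @ x + N * p
            if not events or (abs(c_q @ x_cand) > delta) == hi:
                break
            lo_t, hi_t = 0.0, remaining
            for _ in range(60):
                mid = 0.5 * (lo_t + hi_t)
                Mm, Nm = _rk4_step_matrices(powers[hi], mid)
                if (abs(c_q @ (Mm @ x + Nm * p)) > delta) == hi:
                    lo_t = mid
                else:
                    hi_t = mid
            Mt, Nt = _rk4_step_matrices(powers[hi], lo_t)
            x = Mt @ x + Nt * p  # last point still in the old mode
            remaining -= lo_t
            hi = not hi  # mode flips at the located crossing
        x = x_cand
    if status != "ok":
        t, pset, X, phi_active = t[:end], pset[:end], X[:end], phi_active[:end]
    return _reconstruct(lure, t, pset, X, phi_active, nl.alpha, dt, pattern, status)


def simulate_linear(
    plant: LinearStateSpace,
    ctrl: IntegralController,
    pattern: BreathPattern,
    dt: float = DEFAULT_DT,
    x0: Optional[np.ndarray] = None,
) -> SimResult:
    """Simulate the linear integral-control loop (no switched gain)."""
    return _simulate_switched(plant, ctrl, SwitchNonlinearity(delta=0.0, alpha=0.0),
                              pattern, dt, x0)


def simulate_vgc(
    plant: LinearStateSpace,
    ctrl: IntegralController,
    nl: SwitchNonlinearity,
    pattern: BreathPattern,
    dt: float = DEFAULT_DT,
    x0: Optional[np.ndarray] = None,
) -> SimResult:
    """Simulate the variable-gain loop; φ is evaluated each step from current outputs."""
    return _simulate_switched(plant, ctrl, nl, pattern, dt, x0)


def equilibrium_state(plant: LinearStateSpace, ctrl: IntegralController, p_set: float) -> np.ndarray:
    """Closed-loop equilibrium for a constant set point (e = 0, Q_pat = 0)."""
    lure = assemble_lure(plant, ctrl)
    n = lure.n_states
    rhs = -lure.B * p_set
    return np.linalg.solve(lure.A, rhs)


def _quadratic_node_flow(c: float, a_q: float) -> float:
    """Solve a_q·Q|Q| + Q = c for Q (patient flow at the quadratic-lung node).

    a_q = R_quad·(1/R_hose + 1/R_leak) ≥ 0; the law is odd in c and reduces
    to Q = c when a_q = 0.
    """
    if a_q == 0.0:
        return c
    sign = 1.0 if c >= 0 else -1.0
    cc = abs(c)
    return sign * (math.sqrt(1.0 + 4.0 * a_q * cc) - 1.0) / (2.0 * a_q)


def simulate_vgc_nonlinear_lung(
    params: PatientHoseParams,
    blower_plant: LinearStateSpace,
    ctrl: IntegralController,
    nl: SwitchNonlinearity,
    pattern: BreathPattern,
    quadratic_r: float,
    dt: float = DEFAULT_DT,
    x0: Optional[np.ndarray] = None,
) -> SimResult:
    """Variable-gain loop with a quadratic (orifice-type) lung resistance.

    The linear lung law Δp = R_lung·Q_pat is replaced by
    Δp = R_quad·Q_pat·|Q_pat| (units mbar·s²/L²), as for flow through a
    simple hole; ``params.r_lung`` is ignored.  The pressure-node balance
    then becomes a scalar quadratic in Q_pat and is solved in closed form at
    every integrator stage.  φ is held over each step, as in the linear-lung
    simulator.
    """
    if not quadratic_r >= 0:
        raise ValueError("quadratic_r must be >= 0")
    if not dt > 0:
        raise ValueError("dt must be positive")
    bp = blower_plant.meta["blower"]
    wn2 = bp.omega_n**2
    Ab = blower_plant.A[:2, :2] if blower_plant.n_states > 2 else blower_plant.A
    gh, gk = 1.0 / params.r_hose, 1.0 / params.r_leak
    a_node = gh + gk
    a_q = quadratic_r * a_node
    k_i = ctrl.k_i
    c_lung = params.c_lung

    t, pset = generate_setpoint(pattern, dt)
    nsamp = t.size
    X = np.empty((nsamp, 4))
    phi_active = np.zeros(nsamp, dtype=bool)
    P_aw = np.empty(nsamp)
    Q_pat = np.empty(nsamp)
    x = np.zeros(4) if x0 is None else np.asarray(x0, dtype=float).copy()
    status = "ok"
    end = nsamp

    def outputs(xv: np.ndarray) -> tuple[float, float, float]:
        p_out = wn2 * xv[1]
        c = p_out * gh - a_node * xv[2]
        q = _quadratic_node_flow(c, a_q)
        p_aw = xv[2] + quadratic_r * q * abs(q)
        return p_out, p_aw, q

    def rhs(xv: np.ndarray, p: float, phi: float) -> np.ndarray:
        p_out, p_aw, q = outputs(xv)
        p_ctl = p + k_i * xv[3]
        dxb = Ab @ xv[:2] + np.array([p_ctl, 0.0])
        e = p - p_aw
        return np.array([dxb[0], dxb[1], q / c_lung, (1.0 + phi) * e])

    for k in range(nsamp):
        X[k] = x
        if not np.all(np.abs(x) < OVERFLOW_GUARD):
            status = "diverged"
            end = k + 1
            P_aw[k], Q_pat[k] = np.nan, np.nan
            break
        _, p_aw_k, q_k = outputs(x)
        P_aw[k], Q_pat[k] = p_aw_k, q_k
        phi = phi_gain(nl, q_k)
        phi_active[k] = phi > 0.0
        p = pset[k]
        k1 = rhs(x, p, phi)
        k2 = rhs(x + 0.5 * dt * k1, p, phi)
        k3 = rhs(x + 0.5 * dt * k2, p, phi)
        k4 = rhs(x + dt * k3, p, phi)
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    if status != "ok":
        t, pset, X = t[:end], pset[:end], X[:end]
        phi_active, P_aw, Q_pat = phi_active[:end], P_aw[:end], Q_pat[:end]

    p_out = wn2 * X[:, 1]
    p_lung = X[:, 2]
    p_control = pset + k_i * X[:, 3]
    q_leak = P_aw * gk
    q_out = (p_out - P_aw) * gh
    e = pset - P_aw
    u = -np.where(phi_active, nl.alpha, 0.0) * e
    return SimResult(
        t=t, p_set=pset, p_control=p_control, p_out=p_out, p_aw=P_aw,
        p_lung=p_lung, q_pat=Q_pat, q_leak=q_leak, q_out=q_out, e=e, u=u,
        phi_active=phi_active.astype(np.uint8), delta_p=p_out - P_aw, states=X,
        dt=dt, pattern=pattern, status=status,
        meta={"quadratic_r": quadratic_r, "patient": params, "k_i": k_i},
    )
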