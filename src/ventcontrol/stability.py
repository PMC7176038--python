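"""Circle-criterion / input-to-state-stability checks for the switched loop.

For the Lur'e closed loop (linear low-gain loop in feedback with the
sector-bounded switch nonlinearity) the sufficient ISS conditions are:

1. ``1 + α·G_eu(s)`` strictly positive real, split into
   (a) G_eu Hurwitz, (b) Re G_eu(jω) > −1/α for all ω, and
   (c) 1 + α·G_eu(∞) > 0; and
2. the nonlinearity lies in the sector [0, α].

Condition (b) is a global minimisation of Re G_eu(jω) over frequency; it is
solved by a dense log-grid scan followed by bounded scalar refinement.  The
largest admissible additional gain follows as α_max = −1/min Re (infinite
when the real part never goes negative).  The switching length δ never
enters: it is performance-only, stability-invariant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.optimize

from .controllers import IntegralController, SwitchNonlinearity, phi_gain
from .plant import LinearStateSpace, RationalTF, ss_to_tf
from .simulation import closed_loop_tfs

#: pole real parts must lie below this for a Hurwitz verdict
HURWITZ_TOL = -1e-9
#: strictness slack for the real-part condition (b)
STRICT_SLACK = 1e-12


@dataclass
class StabilityReport:
    """Outcome of the ISS conditions at a given additional gain α."""

    hurwitz: bool
    poles: list
    min_re_geu: float
    argmin_omega: float
    alpha: float
    alpha_max: float
    cond_infinity: float
    cond_a: bool
    cond_b: bool
    cond_c: bool
    sector_ok: Optional[bool] = None
    verdict: Optional[bool] = None
    meta: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d["poles"] = [[complex(p).real, complex(p).imag] for p in self.poles]
        d["alpha_max"] = None if math.isinf(self.alpha_max) else self.alpha_max
        return json.dumps(d, indent=2, default=str, **kwargs)


def hurwitz_check(
    sys: RationalTF | LinearStateSpace, tol: float = HURWITZ_TOL
) -> tuple[bool, np.ndarray]:
    """True iff every pole has real part below ``tol`` (default −1e−9)."""
    if isinstance(sys, LinearStateSpace):
        poles = sys.poles()
    else:
        den = np.asarray(sys.denominators[0])
        if den.size == 0 or not np.any(den):
            raise ValueError("degenerate denominator")
        poles = np.roots(den)
    return bool(np.all(poles.real < tol)), poles


def _freq_grid(
    g: RationalTF, w_lo: float = 1e-3, w_hi: float = 1e5, pts_per_decade: int = 2000
) -> np.ndarray:
    # widen the grid so it covers >= 100x the fastest pole/zero
    roots = list(np.abs(g.poles())) + list(np.abs(np.roots(g.numerators[0])))
    fastest = max([r for r in roots if r > 0], default=0.0)
    w_hi = max(w_hi, 100.0 * fastest)
    decades = math.log10(w_hi / w_lo)
    return np.logspace(math.log10(w_lo), math.log10(w_hi), int(pts_per_decade * decades) + 1)


def real_part_margin(
    g_eu: RationalTF, grid: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """Global minimum of Re G_eu(jω) over ω ∈ [0, ∞) and its argmin frequency.

    A dense log-spaced scan locates the minimising region; bounded scalar
    minimisation refines it.  ω = 0 and the ω → ∞ feedthrough limit are
    included as candidates (argmin reported as 0 or inf respectively).
    """
    if grid is None:
        grid = _freq_grid(g_eu)
    re = g_eu.freq_response(grid)[0].real
    i0 = int(np.argmin(re))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, grid.size - 1)]
    if hi > lo:
        res = scipy.optimize.minimize_scalar(
            lambda lw: float(g_eu.evaluate(1j * math.exp(lw)).real),
            bounds=(math.log(lo), math.log(hi)),
            method="bounded",
            options={"xatol": 1e-14},
        )
        w_min, re_min = math.exp(res.x), float(res.fun)
        if re[i0] < re_min:
            w_min, re_min = grid[i0], float(re[i0])
    else:
        w_min, re_min = grid[i0], float(re[i0])
    # boundary candidates
    re0 = float(g_eu.evaluate(0j).real) if g_eu.denominators[0][-1] != 0 else None
    if re0 is not None and re0 < re_min:
        w_min, re_min = 0.0, re0
    re_inf = g_eu.feedthrough_limit()
    if re_inf < re_min:
        w_min, re_min = math.inf, re_inf
    return re_min, w_min


def alpha_max(min_re: float) -> float:
    """Largest additional gain satisfying Re G_eu > −1/α: −1/min Re, or ∞ if min Re ≥ 0."""
    return math.inf if min_re >= 0 else -1.0 / min_re


def spr_check(g_eu: RationalTF, alpha: float) -> StabilityReport:
    """Evaluate strict positive realness of 1 + α·G_eu (conditions a–c)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    hur, poles = hurwitz_check(g_eu)
    min_re, w_min = real_part_margin(g_eu) if hur else (math.nan, math.nan)
    a_max = alpha_max(min_re) if hur else math.nan
    cond_inf = 1.0 + alpha * g_eu.feedthrough_limit()
    if alpha == 0.0:
        cond_b = True
    else:
        cond_b = hur and (min_re + 1.0 / alpha > STRICT_SLACK)
    return StabilityReport(
        hurwitz=hur,
        poles=list(poles),
        min_re_geu=min_re,
        argmin_omega=w_min,
        alpha=alpha,
        alpha_max=a_max,
        cond_infinity=cond_inf,
        cond_a=hur,
        cond_b=bool(cond_b),
        cond_c=bool(cond_inf > 0.0),
    )


def sector_check(
    nl: SwitchNonlinearity,
    alpha: float,
    q_samples: Iterable[float],
    e_samples: Iterable[float],
) -> bool:
    """True iff 0 ≤ φ(e,Q)/e ≤ α on the sample grids.

    For the switch law φ(Q) ∈ {0, nl.alpha} independent of e, so the check
    reduces to nl.alpha ≤ α; the sampled form is kept as the general
    definition of the sector condition.
    """
    q_samples = list(q_samples)
    e_samples = [e for e in e_samples if e != 0.0]
    if not q_samples or not e_samples:
        raise ValueError("sample grids must be nonempty")
    for q in q_samples:
        g = phi_gain(nl, q)
        if not (0.0 <= g <= alpha):
            return False
    return True


_DEFAULT_Q_SAMPLES = tuple(np.linspace(-3.0, 3.0, 101))  # L/s, spans both branches
_DEFAULT_E_SAMPLES = (-10.0, -1.0, -0.01, 0.01, 1.0, 10.0)  # mbar


def iss_verdict(
    plant: LinearStateSpace,
    ctrl: IntegralController,
    nl: SwitchNonlinearity,
    q_samples: Sequence[float] = _DEFAULT_Q_SAMPLES,
    e_samples: Sequence[float] = _DEFAULT_E_SAMPLES,
) -> StabilityReport:
    """Full ISS report for the switched loop at α = nl.alpha.

    Verdict is true iff 1 + α·G_eu is strictly positive real (a–c) and the
    nonlinearity satisfies the [0, α] sector condition.
    """
    g_eu = closed_loop_tfs(ss_to_tf(plant).channel("p_aw"), ctrl)["G_eu"]
    report = spr_check(g_eu, nl.alpha)
    report.sector_ok = sector_check(nl, nl.alpha, q_samples, e_samples)
    report.verdict = bool(
        report.cond_a and report.cond_b and report.cond_c and report.sector_ok
    )
    report.meta = {"k_i": ctrl.k_i, "delta_l_per_s": nl.delta}
    return report


def bank_alpha_max(
    plants: Iterable[LinearStateSpace], ctrl: IntegralController
) -> tuple[float, list[float]]:
    """α_max over a family of plants: the minimum of the per-plant values.

    Mirrors checking the circle-criterion condition over a large range of
    patient-hose combinations and retaining the worst case.
    """
    per_plant = []
    for plant in plants:
        g_eu = closed_loop_tfs(ss_to_tf(plant).channel("p_aw"), ctrl)["G_eu"]
        hur, _ = hurwitz_check(g_eu)
        if not hur:
            per_plant.append(0.0)
            continue
        min_re, _ = real_part_margin(g_eu)
        per_plant.append(alpha_max(min_re))
    if not per_plant:
        raise ValueError("empty plant family")
    return min(per_plant), per_plant
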