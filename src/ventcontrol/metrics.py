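"""Clinical performance indicators computed from simulation traces.

Three indicators are evaluated per breath and aggregated worst-case:

* 10–90% rise time of the airway pressure over the inspiratory step
  (specification: approximately 0.2 s);
* plateau error, the distance of the end-inspiratory airway pressure from
  the inspiratory target (specification: within ±2 mbar);
* expiratory flow overshoot, the largest positive patient-flow excursion
  after the peak expiratory flow, which is what falsely triggers an
  assisted breath (specification: below the trigger threshold, 2 L/min
  typical).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
import json
from typing import Optional

import numpy as np
import pandas as pd

from .controllers import LMIN_PER_LS
from .simulation import SimResult


@dataclass(frozen=True)
class SpecThresholds:
    """Pass/fail thresholds: rise time (s), plateau band (mbar), trigger flow (L/min)."""

    rise_time_s: float = 0.2
    plateau_mbar: float = 2.0
    overshoot_lmin: float = 2.0


@dataclass
class SpecReport:
    """Worst-case indicator values across breaths with pass flags."""

    rise_time: float
    plateau_error: float
    flow_overshoot: float
    pass_rise: bool
    pass_plateau: bool
    pass_overshoot: bool
    thresholds: SpecThresholds = field(default_factory=SpecThresholds)
    per_breath: Optional[pd.DataFrame] = None

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d.pop("per_breath", None)
        if self.per_breath is not None:
            d["per_breath"] = self.per_breath.to_dict(orient="records")
        return json.dumps(d, indent=2, allow_nan=True, default=float, **kwargs)


def breath_windows(trace: SimResult) -> list[tuple[float, float, float]]:
    """Per-breath timing ``(t_start, t_insp_end, t_end)`` from the trace's pattern."""
    if trace.pattern is None:
        raise ValueError("trace carries no breath pattern")
    p = trace.pattern
    t_end = trace.t[-1]
    windows = []
    for j in range(p.n_breaths):
        t0 = j * p.t_total
        if t0 + p.t_total > t_end + 0.5 * trace.dt:
            break
        windows.append((t0, t0 + p.t_insp, t0 + p.t_total))
    return windows


def _slice(trace: SimResult, t0: float, t1: float) -> slice:
    i0 = int(np.searchsorted(trace.t, t0 - 1e-12))
    i1 = int(np.searchsorted(trace.t, t1 - 1e-12, side="right"))
    if i1 <= i0:
        raise ValueError(f"empty window [{t0}, {t1}]")
    return slice(i0, i1)


def rise_time_10_90(
    trace: SimResult,
    window: tuple[float, float],
    levels: Optional[tuple[float, float]] = None,
) -> float:
    """10–90% rise time of p_aw over a rising set-point step, in seconds.

    ``levels`` defaults to (peep, p_insp) from the trace's pattern; the band
    edges are peep + 0.1Δ and peep + 0.9Δ with Δ = p_insp − peep.  Crossing
    times use linear interpolation between samples.  Returns NaN when the
    90% level is never reached inside the window.
    """
    if levels is None:
        if trace.pattern is None:
            raise ValueError("levels required when trace has no pattern")
        levels = (trace.pattern.peep, trace.pattern.p_insp)
    lo, hi = levels
    delta = hi - lo
    sl = _slice(trace, *window)
    t = trace.t[sl]
    y = trace.p_aw[sl]

    def first_crossing(level: float) -> float:
        above = y >= level
        if not above.any():
            return math.nan
        i = int(np.argmax(above))
        if i == 0:
            return t[0]
        # linear interpolation between samples i-1 and i
        f = (level - y[i - 1]) / (y[i] - y[i - 1])
        return t[i - 1] + f * (t[i] - t[i - 1])

    t10 = first_crossing(lo + 0.1 * delta)
    t90 = first_crossing(lo + 0.9 * delta)
    if math.isnan(t10) or math.isnan(t90):
        return math.nan
    return max(t90 - t10, 0.0)


def plateau_error(
    trace: SimResult, window: tuple[float, float], target: Optional[float] = None
) -> float:
    """|plateau pressure − target| in mbar.

    The plateau pressure is the mean airway pressure over the final 5% of
    the inspiration window (suppresses sampling noise).
    """
    if target is None:
        if trace.pattern is None:
            raise ValueError("target required when trace has no pattern")
        target = trace.pattern.p_insp
    t0, t1 = window
    sl = _slice(trace, t1 - 0.05 * (t1 - t0), t1)
    return abs(float(np.mean(trace.p_aw[sl])) - target)


def flow_overshoot(trace: SimResult, window: tuple[float, float]) -> float:
    """Largest positive patient flow after the peak expiratory flow, in L/min.

    Within the expiration window the patient flow is negative (air leaving
    the lung); any positive rebound after the (negative) peak is the
    overshoot that can falsely trigger an inspiration.  Zero if the flow
    never becomes positive.
    """
    sl = _slice(trace, *window)
    q = trace.q_pat[sl]
    i_peak = int(np.argmin(q))
    tail = q[i_peak:]
    return max(float(tail.max()), 0.0) * LMIN_PER_LS


def evaluate_specs(
    trace: SimResult, thresholds: SpecThresholds = SpecThresholds()
) -> SpecReport:
    """Per-breath indicators aggregated worst-case into a SpecReport.

    Worst case means the largest rise time (NaN if any breath never reaches
    the 90% band), the largest plateau error and the largest overshoot,
    since the specifications are safety-style bounds.
    """
    windows = breath_windows(trace)
    if not windows:
        raise ValueError("trace does not contain a full breath")
    rows = []
    for j, (t0, t_ie, t1) in enumerate(windows):
        rows.append(
            {
                "breath": j,
                "rise_time_s": rise_time_10_90(trace, (t0, t_ie)),
                "plateau_error_mbar": plateau_error(trace, (t0, t_ie)),
                "flow_overshoot_lmin": flow_overshoot(trace, (t_ie, t1)),
            }
        )
    df = pd.DataFrame(rows)
    rise = float(df["rise_time_s"].max(skipna=False))
    plat = float(df["plateau_error_mbar"].max())
    over = float(df["flow_overshoot_lmin"].max())
    return SpecReport(
        rise_time=rise,
        plateau_error=plat,
        flow_overshoot=over,
        pass_rise=bool(not math.isnan(rise) and rise <= thresholds.rise_time_s),
        pass_plateau=bool(plat <= thresholds.plateau_mbar),
        pass_overshoot=bool(over <= thresholds.overshoot_lmin),
        thresholds=thresholds,
        per_breath=df,
    )
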