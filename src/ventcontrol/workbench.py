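"""Patient-bank generation, parameter sweeps, and scenario comparison.

The patient bank emulates a large range of patient–hose combinations by
log-uniform sampling of the four circuit parameters around a preset (the
true family of lungs seen by a ventilator is not tabulated anywhere; a
decade centred on the nominal values is shipped as fixture policy, clearly
a non-physiological-survey choice).  Sweeps reproduce the two study axes:
integral gain k_i (linear tradeoff) and switching length δ (variable-gain
tradeoff), reporting tidy tables of the three performance indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .controllers import IntegralController, LMIN_PER_LS, SwitchNonlinearity
from .metrics import SpecReport, SpecThresholds, evaluate_specs
from .plant import (
    BlowerParams,
    LinearStateSpace,
    PatientHoseParams,
    build_blower_ss,
    build_patient_hose_ss,
    couple_plant,
)
from .simulation import BreathPattern, SimResult, simulate_linear, simulate_vgc

#: sweep scenario: slow enough that the slowest controller's 10-90% rise
#: completes within the inspiration, so the metric is defined at every point
SWEEP_PATTERN = BreathPattern(peep=5.0, p_insp=20.0, rate=10.0, ie_ratio=0.5, n_breaths=3)


@dataclass(frozen=True)
class PatientBank:
    """Reproducible family of patient-hose parameter sets."""

    members: tuple[tuple[str, PatientHoseParams], ...]
    ranges: Mapping[str, tuple[float, float]]
    seed: int

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def plants(self, blower: BlowerParams = BlowerParams()) -> list[LinearStateSpace]:
        b = build_blower_ss(blower)
        return [couple_plant(build_patient_hose_ss(p), b) for _, p in self.members]


def default_bank_ranges(
    nominal: PatientHoseParams, half_decades: float = 0.5
) -> dict[str, tuple[float, float]]:
    """One decade (by default) centred on the nominal parameters, per axis."""
    f = 10.0**half_decades
    return {
        name: (value / f, value * f)
        for name, value in (
            ("r_lung", nominal.r_lung),
            ("c_lung", nominal.c_lung),
            ("r_hose", nominal.r_hose),
            ("r_leak", nominal.r_leak),
        )
    }


def generate_patient_bank(
    ranges: Mapping[str, tuple[float, float]], n: int, seed: int
) -> PatientBank:
    """Log-uniform samples of (R_lung, C_lung, R_hose, R_leak); deterministic under seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    keys = ("r_lung", "c_lung", "r_hose", "r_leak")
    for k in keys:
        lo, hi = ranges[k]
        if not (0 < lo <= hi) or not math.isfinite(hi):
            raise ValueError(f"invalid range for {k}: {(lo, hi)}")
    rng = np.random.default_rng(seed)
    members = []
    for i in range(n):
        draw = {}
        for k in keys:
            lo, hi = ranges[k]
            draw[k] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        members.append((f"patient_{i:03d}", PatientHoseParams(**draw)))
    return PatientBank(members=tuple(members), ranges=dict(ranges), seed=seed)


def _metric_row(report: SpecReport, status: str) -> dict:
    return {
        "rise_time_s": report.rise_time,
        "plateau_error_mbar": report.plateau_error,
        "flow_overshoot_lmin": report.flow_overshoot,
        "pass_rise": report.pass_rise,
        "pass_plateau": report.pass_plateau,
        "pass_overshoot": report.pass_overshoot,
        "status": status,
    }


def ki_sweep(
    plant: LinearStateSpace,
    ki_values: Sequence[float],
    pattern: BreathPattern = SWEEP_PATTERN,
    thresholds: SpecThresholds = SpecThresholds(),
    dt: float = 1e-3,
    label: str = "nominal",
) -> pd.DataFrame:
    """Linear-controller tradeoff: indicators as a function of the integral gain.

    Unstable or diverging runs are recorded with their status rather than
    raised, so the sweep always completes.
    """
    rows = []
    for ki in ki_values:
        if ki <= 0:
            raise ValueError("ki values must be positive")
        res = simulate_linear(plant, IntegralController(ki), pattern, dt=dt)
        try:
            rep = evaluate_specs(res, thresholds)
            row = _metric_row(rep, res.status)
        except ValueError:
            row = _metric_row(
                SpecReport(math.nan, math.nan, math.nan, False, False, False), res.status
            )
        rows.append({"k_i": ki, "fixture": label, **row})
    return pd.DataFrame(rows)


def delta_sweep(
    plant: LinearStateSpace,
    ctrl: IntegralController,
    alpha: float,
    delta_values_lmin: Sequence[float],
    pattern: BreathPattern = SWEEP_PATTERN,
    thresholds: SpecThresholds = SpecThresholds(),
    dt: float = 1e-3,
    label: str = "nominal",
) -> pd.DataFrame:
    """Variable-gain tradeoff: indicators as a function of the switching length δ.

    δ = 0 is the frozen high-gain linear controller C(s)(1+α); δ above the
    peak patient flow reduces to the low-gain linear controller.
    """
    rows = []
    for d in delta_values_lmin:
        if d < 0:
            raise ValueError("delta values must be >= 0")
        nl = SwitchNonlinearity.from_lmin(d, alpha)
        res = simulate_vgc(plant, ctrl, nl, pattern, dt=dt)
        try:
            rep = evaluate_specs(res, thresholds)
            row = _metric_row(rep, res.status)
        except ValueError:
            row = _metric_row(
                SpecReport(math.nan, math.nan, math.nan, False, False, False), res.status
            )
        rows.append({"delta_lmin": d, "fixture": label, **row})
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """Aligned low-gain / high-gain / variable-gain runs with their reports."""

    traces: dict[str, SimResult]
    reports: dict[str, SpecReport]
    table: pd.DataFrame


def run_comparison(
    plant: LinearStateSpace,
    ctrl: IntegralController,
    alpha: float,
    delta_lmin: float,
    pattern: BreathPattern = SWEEP_PATTERN,
    thresholds: SpecThresholds = SpecThresholds(),
    dt: float = 1e-3,
) -> ComparisonResult:
    """Side-by-side low-gain, high-gain and variable-gain scenarios.

    All three runs share the pattern and integrator settings.  The
    high-gain scenario is realised as the δ = 0 limit of the switched
    controller (the frozen C(s)(1+α) law), so the variable-gain trace
    coincides with it exactly until the first down-switch.
    """
    scenarios = {
        "low": simulate_linear(plant, ctrl, pattern, dt=dt),
        "high": simulate_vgc(
            plant, ctrl, SwitchNonlinearity.from_lmin(0.0, alpha), pattern, dt=dt
        ),
        "vgc": simulate_vgc(
            plant, ctrl, SwitchNonlinearity.from_lmin(delta_lmin, alpha), pattern, dt=dt
        ),
    }
    reports = {k: evaluate_specs(v, thresholds) for k, v in scenarios.items()}
    table = pd.DataFrame(
        [{"scenario": k, **_metric_row(r, scenarios[k].status)} for k, r in reports.items()]
    )
    return ComparisonResult(traces=scenarios, reports=reports, table=table)
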