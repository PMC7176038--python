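"""Pressure controllers: the linear integral law and the flow-switched gain.

The baseline controller is a pure integrator C(s) = k_i/s acting on the
airway-pressure error e = p_set − p_aw, on top of a unity set-point
feedforward.  The variable-gain element adds an extra error injection
φ(e, Q_pat) = φ(Q_pat)·e upstream of the integrator, where the gain switches
on the magnitude of the patient flow: zero gain while |Q_pat| ≤ δ (lung
nearly full, steady hose drop, keep the flow response quiet) and an
additional gain α while |Q_pat| > δ (pressure build-up/release, compensate
the hose drop fast).  φ lies in the sector [0, α] for every (e, Q_pat),
irrespective of δ — δ is a pure performance knob, never a stability one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .plant import RationalTF

#: L/min per L/s
LMIN_PER_LS = 60.0


@dataclass(frozen=True)
class IntegralController:
    """Integral pressure controller C(s) = k_i/s, with k_i in s^-1 ≥ 0."""

    k_i: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k_i) and self.k_i >= 0):
            raise ValueError(f"k_i must be finite and >= 0, got {self.k_i!r}")


@dataclass(frozen=True)
class SwitchNonlinearity:
    """Flow-switched gain element.

    ``delta`` is the switching length in L/s (internal canonical flow unit;
    use :meth:`from_lmin` for the conventional L/min figure) and ``alpha``
    the dimensionless additional gain.
    """

    delta: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.delta >= 0):
            raise ValueError(f"delta must be >= 0, got {self.delta!r}")
        if not (math.isfinite(self.alpha) and self.alpha >= 0):
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha!r}")

    @classmethod
    def from_lmin(cls, delta_lmin: float, alpha: float) -> "SwitchNonlinearity":
        """Construct with the switching length given in L/min."""
        return cls(delta=delta_lmin / LMIN_PER_LS, alpha=alpha)

    @property
    def delta_lmin(self) -> float:
        return self.delta * LMIN_PER_LS


def controller_tf(ctrl: IntegralController) -> RationalTF:
    """Transfer function k_i/s of the integral controller."""
    return RationalTF(
        numerators=((ctrl.k_i,),),
        denominators=((1.0, 0.0),),
        input_label="e",
        output_labels=("p_fb",),
    )


def phi_gain(nl: SwitchNonlinearity, q_pat: float) -> float:
    """Switched gain φ(Q_pat): 0 while |Q_pat| ≤ δ, else α.

    The boundary |Q_pat| = δ belongs to the low-gain branch.
    """
    return 0.0 if abs(q_pat) <= nl.delta else nl.alpha


def vgc_injection(nl: SwitchNonlinearity, e: float, q_pat: float) -> float:
    """Injected signal φ(e, Q_pat) = φ(Q_pat)·e in mbar.

    Linear in e, hence sector-bounded: 0 ≤ φ(e,Q)/e ≤ α for all e ≠ 0.
    """
    return phi_gain(nl, q_pat) * e


def effective_gain(ctrl: IntegralController, nl: SwitchNonlinearity, q_pat: float) -> float:
    """Instantaneous integral gain k_i·(1 + φ(Q_pat)) of the switched loop.

    Equals k_i in the low-gain region and k_i·(1+α) in the high-gain region;
    the δ=0 limit is the frozen high-gain linear controller C(s)(1+α).
    """
    return ctrl.k_i * (1.0 + phi_gain(nl, q_pat))
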