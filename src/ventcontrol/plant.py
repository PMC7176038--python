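"""Lumped-parameter models of the patient–hose–leak circuit and the blower.

The physical picture is a single-compartment lung (resistance ``R_lung``,
compliance ``C_lung``) fed through a hose (``R_hose``) with an intentional
leak orifice near the mouth (``R_leak``) that flushes exhaled CO2-rich air.
A centrifugal blower pressurises the circuit; its inertia is modelled as a
critically-damped second-order low-pass from the commanded pressure
``p_control`` to the module outlet pressure ``p_out``.

All quantities use canonical internal units: pressure mbar, flow L/s,
volume L, time s, resistance mbar·s/L, compliance L/mbar.  The config layer
(:mod:`ventcontrol.config`) converts from the conventional reporting units
(L/min for flows, mL/mbar for compliance) at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.signal


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class PatientHoseParams:
    """Lumped patient–hose circuit parameters.

    Attributes
    ----------
    r_lung : float
        Lung resistance, mbar·s/L.
    c_lung : float
        Lung compliance, L/mbar.
    r_hose : float
        Hose resistance, mbar·s/L.
    r_leak : float
        Leak resistance, mbar·s/L.
    """

    r_lung: float
    c_lung: float
    r_hose: float
    r_leak: float

    def __post_init__(self) -> None:
        _require_positive(
            r_lung=self.r_lung, c_lung=self.c_lung, r_hose=self.r_hose, r_leak=self.r_leak
        )


@dataclass(frozen=True)
class BlowerParams:
    """Second-order blower actuator parameters.

    ``omega_n`` is the natural angular frequency in rad/s and ``zeta`` the
    dimensionless damping ratio.  The defaults (2π·30 rad/s, critically
    damped) correspond to a typical turbine blower.
    """

    omega_n: float = 2.0 * math.pi * 30.0
    zeta: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(omega_n=self.omega_n, zeta=self.zeta)


@dataclass(frozen=True)
class LinearStateSpace:
    """A labelled LTI state-space system ``(A, B, C, D)``.

    Labels are authoritative: downstream code looks up channels by name,
    never by position.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    state_labels: tuple[str, ...]
    input_labels: tuple[str, ...]
    output_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        n = A.shape[0]
        B = np.asarray(self.B, dtype=float).reshape(n, -1)
        m = B.shape[1]
        C = np.asarray(self.C, dtype=float).reshape(-1, n)
        p = C.shape[0]
        D = np.asarray(self.D, dtype=float).reshape(p, m)
        if A.shape != (n, n):
            raise ValueError("A must be square")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "D", D)
        for labels, dim, what in (
            (self.state_labels, n, "state"),
            (self.input_labels, m, "input"),
            (self.output_labels, p, "output"),
        ):
            if len(labels) != dim:
                raise ValueError(f"{what} labels {labels} do not match dimension {dim}")
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {what} labels: {labels}")

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    def output_index(self, label: str) -> int:
        return self.output_labels.index(label)

    def freq_response(self, omega: np.ndarray) -> np.ndarray:
        """Frequency response ``C (jωI − A)^-1 B + D``.

        Returns a complex array of shape ``(p, m, len(omega))``.
        """
        omega = np.atleast_1d(np.asarray(omega, dtype=float))
        n = self.n_states
        out = np.empty((self.C.shape[0], self.B.shape[1], omega.size), dtype=complex)
        eye = np.eye(n)
        for k, w in enumerate(omega):
            out[:, :, k] = self.C @ np.linalg.solve(1j * w * eye - self.A, self.B) + self.D
        return out

    def poles(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)


@dataclass(frozen=True)
class RationalTF:
    """Per-channel rational transfer functions in descending powers of s."""

    numerators: tuple[tuple[float, ...], ...]
    denominators: tuple[tuple[float, ...], ...]
    input_label: str
    output_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        nums = tuple(tuple(float(c) for c in num) for num in self.numerators)
        dens = tuple(tuple(float(c) for c in den) for den in self.denominators)
        if len(nums) != len(dens) or len(nums) != len(self.output_labels):
            raise ValueError("channel count mismatch between numerators/denominators/labels")
        for num, den in zip(nums, dens):
            if len(den) == 0 or den[0] == 0.0:
                raise ValueError("denominator leading coefficient must be nonzero")
            if len(num) > len(den):
                raise ValueError("transfer function must be proper (num degree <= den degree)")
        object.__setattr__(self, "numerators", nums)
        object.__setattr__(self, "denominators", dens)

    @property
    def n_channels(self) -> int:
        return len(self.numerators)

    def channel(self, label: str) -> "RationalTF":
        i = self.output_labels.index(label)
        return RationalTF(
            (self.numerators[i],), (self.denominators[i],), self.input_label, (label,)
        )

    def evaluate(self, s: complex | np.ndarray, channel: int = 0) -> np.ndarray:
        num = np.asarray(self.numerators[channel])
        den = np.asarray(self.denominators[channel])
        return np.polyval(num, s) / np.polyval(den, s)

    def freq_response(self, omega: np.ndarray) -> np.ndarray:
        """Complex response per channel, shape ``(n_channels, len(omega))``."""
        omega = np.atleast_1d(np.asarray(omega, dtype=float))
        s = 1j * omega
        return np.vstack([self.evaluate(s, i) for i in range(self.n_channels)])

    def feedthrough_limit(self, channel: int = 0) -> float:
        """Value as s → ∞: zero if strictly proper, leading-coefficient ratio if biproper."""
        num = self.numerators[channel]
        den = self.denominators[channel]
        if len(num) < len(den) or len(num) == 0:
            return 0.0
        return num[0] / den[0]

    def poles(self, channel: int = 0) -> np.ndarray:
        return np.roots(self.denominators[channel])


def build_patient_hose_ss(params: PatientHoseParams) -> LinearStateSpace:
    """Patient–hose–leak dynamics as a one-state system.

    State ``p_lung``; input ``p_out``; outputs ``[p_aw, Q_pat]``.  The airway
    pressure is the resistive-divider node value and the lung pressure
    integrates the patient flow through the compliance.
    """
    gl, gh, gk = 1.0 / params.r_lung, 1.0 / params.r_hose, 1.0 / params.r_leak
    s_tot = gl + gh + gk
    rc = params.r_lung * params.c_lung
    a_h = -(gh + gk) / (rc * s_tot)
    b_h = gh / (rc * s_tot)
    # p_aw = (p_lung/R_lung + p_out/R_hose) / (1/R_lung + 1/R_hose + 1/R_leak)
    c_paw = gl / s_tot
    d_paw = gh / s_tot
    # Q_pat = (p_aw - p_lung) / R_lung
    c_q = -(gh + gk) / (params.r_lung * s_tot)
    d_q = gh / (params.r_lung * s_tot)
    return LinearStateSpace(
        A=[[a_h]],
        B=[[b_h]],
        C=[[c_paw], [c_q]],
        D=[[d_paw], [d_q]],
        state_labels=("p_lung",),
        input_labels=("p_out",),
        output_labels=("p_aw", "Q_pat"),
        meta={"patient": params},
    )


def build_blower_ss(params: BlowerParams) -> LinearStateSpace:
    """Blower actuator: second-order low-pass from ``p_control`` to ``p_out``."""
    wn, z = params.omega_n, params.zeta
    return LinearStateSpace(
        A=[[-2.0 * z * wn, -wn * wn], [1.0, 0.0]],
        B=[[1.0], [0.0]],
        C=[[0.0, wn * wn]],
        D=[[0.0]],
        state_labels=("x_b1", "x_b2"),
        input_labels=("p_control",),
        output_labels=("p_out",),
        meta={"blower": params},
    )


def ss_to_tf(sys: LinearStateSpace) -> RationalTF:
    """Convert a single-input state-space system to per-output transfer functions."""
    if sys.B.shape[1] != 1:
        raise ValueError("ss_to_tf supports single-input systems only")
    num, den = scipy.signal.ss2tf(sys.A, sys.B, sys.C, sys.D)
    nums = tuple(tuple(row) for row in np.atleast_2d(num))
    return RationalTF(
        numerators=nums,
        denominators=tuple(tuple(den) for _ in nums),
        input_label=sys.input_labels[0],
        output_labels=sys.output_labels,
    )


def patient_hose_tf(params: PatientHoseParams) -> RationalTF:
    """Transfer functions ``[p_aw/p_out, Q_pat/p_out]`` of the hose circuit."""
    return ss_to_tf(build_patient_hose_ss(params))


def blower_tf(params: BlowerParams) -> RationalTF:
    return ss_to_tf(build_blower_ss(params))


def couple_plant(hose: LinearStateSpace, blower: LinearStateSpace) -> LinearStateSpace:
    """Series coupling of blower and hose: the pressure plant ``P(s)``.

    State ordering ``[x_b1, x_b2, p_lung]``; input ``p_control``; outputs
    ``[p_aw, Q_pat]``.  The frequency response factorises as B(s)·H(s).
    """
    if hose.input_labels != blower.output_labels:
        raise ValueError(
            f"hose input {hose.input_labels} must be driven by blower output "
            f"{blower.output_labels}"
        )
    nb = blower.n_states
    nh = hose.n_states
    A = np.block(
        [
            [blower.A, np.zeros((nb, nh))],
            [hose.B @ blower.C, hose.A],
        ]
    )
    B = np.vstack([blower.B, np.zeros((nh, 1))])
    C = np.hstack([hose.D @ blower.C, hose.C])
    D = hose.D @ blower.D
    return LinearStateSpace(
        A=A,
        B=B,
        C=C,
        D=D,
        state_labels=blower.state_labels + hose.state_labels,
        input_labels=blower.input_labels,
        output_labels=hose.output_labels,
        meta={**blower.meta, **hose.meta},
    )


def dc_gain(sys: LinearStateSpace | RationalTF) -> np.ndarray:
    """Per-channel steady-state gain.

    For a state-space system this is ``-C A^-1 B + D`` and requires ``A``
    Hurwitz; for a transfer function, the ratio of constant terms.
    """
    if isinstance(sys, LinearStateSpace):
        poles = sys.poles()
        if np.any(poles.real >= 0):
            raise ValueError(f"dc_gain undefined: system not asymptotically stable, poles {poles}")
        return (-sys.C @ np.linalg.solve(sys.A, sys.B) + sys.D).ravel()
    gains = []
    for num, den in zip(sys.numerators, sys.denominators):
        if den[-1] == 0.0:
            raise ValueError("dc_gain undefined: pole at s=0")
        gains.append((num[-1] if num else 0.0) / den[-1])
    return np.asarray(gains)


def pressure_dc_gain_closed_form(params: PatientHoseParams) -> float:
    """Steady-state p_aw/p_control: the leak/hose resistive divider R_leak/(R_leak+R_hose).

    At equilibrium the lung is full (Q_pat = 0), so the only flow runs from
    the blower through the hose into the leak, and the hose drop sets the
    attenuation.  Strictly below 1 for any physical (positive) hose resistance.
    """
    return params.r_leak / (params.r_leak + params.r_hose)
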