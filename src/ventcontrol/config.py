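"""Config-file loading and unit conversion at the package boundary.

YAML scenario files use the conventional reporting units (compliance in
mL/mbar, flows and switching lengths in L/min, blower natural frequency in
Hz) and are converted here to the canonical internal units (L/mbar, L/s,
rad/s).  A nominal preset ships with the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .controllers import IntegralController, SwitchNonlinearity
from .metrics import SpecThresholds
from .plant import (
    BlowerParams,
    LinearStateSpace,
    PatientHoseParams,
    build_blower_ss,
    build_patient_hose_ss,
    couple_plant,
)
from .simulation import BreathPattern


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation scenario in canonical units."""

    patient: PatientHoseParams
    blower: BlowerParams
    controller: IntegralController
    nonlinearity: SwitchNonlinearity
    pattern: BreathPattern
    specs: SpecThresholds

    def plant(self) -> LinearStateSpace:
        return couple_plant(build_patient_hose_ss(self.patient), build_blower_ss(self.blower))


def _parse(raw: dict) -> Scenario:
    pat = raw["patient"]
    patient = PatientHoseParams(
        r_lung=float(pat["r_lung"]),
        c_lung=float(pat["c_lung_ml_per_mbar"]) / 1000.0,  # mL/mbar -> L/mbar
        r_hose=float(pat["r_hose"]),
        r_leak=float(pat["r_leak"]),
    )
    blw = raw.get("blower", {})
    blower = BlowerParams(
        omega_n=2.0 * math.pi * float(blw.get("f_n_hz", 30.0)),
        zeta=float(blw.get("zeta", 1.0)),
    )
    ctl = raw.get("controller", {})
    controller = IntegralController(k_i=float(ctl.get("k_i", 0.4)))
    nonlinearity = SwitchNonlinearity.from_lmin(
        delta_lmin=float(ctl.get("delta_lmin", 6.0)), alpha=float(ctl.get("alpha", 0.0))
    )
    ptn = raw.get("pattern", {})
    pattern = BreathPattern(
        peep=float(ptn.get("peep", 5.0)),
        p_insp=float(ptn.get("p_insp", 20.0)),
        rate=float(ptn.get("rate", 15.0)),
        ie_ratio=float(ptn.get("ie_ratio", 0.5)),
        rise_time=float(ptn.get("rise_time", 0.0)),
        n_breaths=int(ptn.get("n_breaths", 3)),
    )
    spc = raw.get("specs", {})
    specs = SpecThresholds(
        rise_time_s=float(spc.get("rise_time_s", 0.2)),
        plateau_mbar=float(spc.get("plateau_mbar", 2.0)),
        overshoot_lmin=float(spc.get("overshoot_lmin", 2.0)),
    )
    return Scenario(patient, blower, controller, nonlinearity, pattern, specs)


def load_scenario(path: str | Path) -> Scenario:
    """Load a YAML scenario file."""
    with open(path) as fh:
        return _parse(yaml.safe_load(fh))


def nominal_scenario() -> Scenario:
    """The shipped nominal preset (patient, blower, controller, pattern, specs)."""
    text = resources.files("ventcontrol").joinpath("presets/nominal.yaml").read_text()
    return _parse(yaml.safe_load(text))
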