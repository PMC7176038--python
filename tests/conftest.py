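import numpy as np
import pytest

import ventcontrol as vc

# The worked fixture used throughout: a mid-size lung on a standard hose.
F1 = dict(r_lung=5.0, c_lung=0.02, r_hose=6.0, r_leak=48.0)


@pytest.fixture(scope="session")
def f1_params() -> vc.PatientHoseParams:
    return vc.PatientHoseParams(**F1)


@pytest.fixture(scope="session")
def blower_params() -> vc.BlowerParams:
    return vc.BlowerParams()


@pytest.fixture(scope="session")
def plant(f1_params, blower_params) -> vc.LinearStateSpace:
    return vc.couple_plant(vc.build_patient_hose_ss(f1_params), vc.build_blower_ss(blower_params))


@pytest.fixture(scope="session")
def low_gain() -> vc.IntegralController:
    return vc.IntegralController(0.4)


@pytest.fixture(scope="session")
def g_eu(plant, low_gain) -> vc.RationalTF:
    return vc.closed_loop_tfs(vc.ss_to_tf(plant).channel("p_aw"), low_gain)["G_eu"]


@pytest.fixture(scope="session")
def sweep_pattern() -> vc.BreathPattern:
    return vc.SWEEP_PATTERN


def make_trace(t, p_aw, q_pat=None, pattern=None) -> vc.SimResult:
    """Minimal synthetic SimResult for metric tests: only p_aw/q_pat matter."""
    t = np.asarray(t, dtype=float)
    p_aw = np.asarray(p_aw, dtype=float)
    q_pat = np.zeros_like(t) if q_pat is None else np.asarray(q_pat, dtype=float)
    z = np.zeros_like(t)
    return vc.SimResult(
        t=t, p_set=z, p_control=z, p_out=z, p_aw=p_aw, p_lung=z, q_pat=q_pat,
        q_leak=z, q_out=z, e=z, u=z, phi_active=z.astype(np.uint8), delta_p=z,
        states=np.zeros((t.size, 4)), dt=float(t[1] - t[0]) if t.size > 1 else 1.0,
        pattern=pattern,
    )
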