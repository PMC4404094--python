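import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import weighbridge as wb

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bridge():
    return wb.BridgeParams()


@pytest.fixture(scope="session")
def calib(bridge):
    """Calibration model fitted from a simulated 4-week standard-weight log."""
    return wb.fit_gain(wb.simulate_calibration_log(bridge, seed=7))


@pytest.fixture(scope="session")
def ensemble(bridge):
    """200 clean single crossings, masses 2-8 kg, with ground truth."""
    return wb.accuracy_ensemble(n=200, seed=1, bp=bridge)


@pytest.fixture(scope="session")
def ensemble_estimates(ensemble, calib):
    cfg = wb.ensemble_config()
    return [(sim, wb.estimate_weight(sim.event, calib, cfg)) for sim in ensemble]


@pytest.fixture(scope="session")
def single_sim(bridge):
    """One typical single crossing (4.5 kg, out) with ground truth."""
    gp = wb.GaitParams(mass=4.5, crossing_speed=0.2, direction="out", seed=3)
    return wb.simulate_crossing(gp, bridge, rng=np.random.default_rng(3))


def constant_trace(n=600, dt=0.005, wgt1=400.0, wgt2=200.0, event_time=None):
    t = np.round(np.arange(n) * dt, 6)
    return wb.ForceTrace(t, np.full(n, float(wgt1)), np.full(n, float(wgt2)), event_time)
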