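import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from phagedyn.model import NondimParams, PopulationState, _rhs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

WT = NondimParams(kappa=1.0, b=28.0, f=0.75)
WT_INIT = PopulationState(0.02, 0.0, 2e-4 * 0.02)


def euler_oracle(p: NondimParams, init: PopulationState, tau_end: float,
                 tau_out: np.ndarray, dtau: float = 1e-4) -> np.ndarray:
    """Fixed-step forward-Euler integration of the scaled model; returns
    the (3, len(tau_out)) state sampled on tau_out.  Deliberately naive —
    an independent check on the adaptive integrator."""
    n = int(round(tau_end / dtau))
    y = init.as_array().copy()
    out = np.empty((3, len(tau_out)))
    k = 0
    for i in range(n + 1):
        tau = i * dtau
        while k < len(tau_out) and tau >= tau_out[k] - 1e-12:
            out[:, k] = y
            k += 1
        y = y + dtau * _rhs(y[0], y[1], y[2], p)
    while k < len(tau_out):
        out[:, k] = y
        k += 1
    return out


@pytest.fixture(scope="session")
def wt_params() -> NondimParams:
    return WT


@pytest.fixture(scope="session")
def wt_init() -> PopulationState:
    return WT_INIT
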