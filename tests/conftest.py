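import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pyracipe as pr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toggle():
    return pr.toggle_switch()


@pytest.fixture(scope="session")
def toggle_ranges(toggle):
    return pr.build_parameter_ranges(toggle, rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def fast_solver():
    """Solver settings for quick unit tests (coarser convergence check)."""
    return pr.SolverConfig(method="rk4", dt=0.1, t_window=10.0, max_windows=100)


def symmetric_toggle_params():
    """The strongly bistable symmetric toggle switch used as a dynamics
    fixture: G=50, k=0.5, B0=10, n=4, lambda=0.01 on both links."""
    return pr.ParamSet(
        production=np.array([50.0, 50.0]),
        degradation=np.array([0.5, 0.5]),
        threshold=np.array([10.0, 10.0]),
        hill=np.array([4.0, 4.0]),
        fold_change=np.array([0.01, 0.01]),
    )


@pytest.fixture()
def toggle_params():
    return symmetric_toggle_params()
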