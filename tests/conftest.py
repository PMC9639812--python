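import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from odelay import DEFAULT_GROWTH, Condition, HICA
from odelay.containers import ODTrace
from odelay.popdyn import default_secretion, simulate_culture

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def growth():
    return DEFAULT_GROWTH


@pytest.fixture(scope="session")
def secretion():
    return default_secretion(DEFAULT_GROWTH)


@pytest.fixture(scope="session")
def make_killed_trace():
    """Noisy trace factory for a given kill fraction (default instrument noise)."""

    def _make(d, seed, horizon=75.0, noise_sd=0.02, p=DEFAULT_GROWTH):
        traj = simulate_culture(p, d, horizon)
        od = traj.od
        if noise_sd > 0:
            rng = np.random.default_rng(seed)
            od = od * np.exp(rng.normal(0.0, noise_sd, od.shape))
            od = np.clip(od + rng.normal(0.0, noise_sd / 10.0, od.shape), 0.0, None)
        return ODTrace(f"d{d}_s{seed}", traj.t * 60.0, od)

    return _make


@pytest.fixture
def exponential_trace():
    """Noise-free pure exponential at the default rate (K effectively infinite)."""
    import math

    t_min = np.arange(0, 75 * 60 + 1, dtype=float)
    od = 0.005 * np.exp(DEFAULT_GROWTH.r * t_min / 60.0)
    return ODTrace("exp", t_min, od)
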