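import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungsim import run_passive_closed_loop, simulate_active
from lungsim.presets import get_preset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def normal_preset():
    return get_preset("normal")


@pytest.fixture(scope="session")
def normal_active_series(normal_preset):
    """Five breaths of the normal spontaneous-breathing scenario."""
    p = normal_preset
    return simulate_active(p.mechanics, p.profile, duration=5 * p.profile.period)


@pytest.fixture(scope="session")
def passive_run_cd60():
    """One default closed-loop passive run (Cd=60, seeded)."""
    return run_passive_closed_loop(Cd=60, seed=1)


@pytest.fixture(autouse=True)
def _no_envelope_warnings_noise():
    # presets legitimately sit below the advertised small-airway range;
    # keep test output clean without hiding unexpected warnings elsewhere
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*envelope.*", category=UserWarning)
        warnings.filterwarnings("ignore", message=".*adjustable range.*", category=UserWarning)
        yield


def rng(seed=0):
    return np.random.default_rng(seed)
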