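import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import optobind as ob

settings.register_profile(
    "derandomized",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def ha4_truth():
    """HA4-regime simulation truth, default triplicate-style settings."""
    return ob.preset_truth("ha4", seed=11)


@pytest.fixture(scope="session")
def ha4_noise_free():
    truth = ob.preset_truth("ha4", noise_sd=0.0, seed=11)
    return truth, ob.simulate_dataset(truth)


@pytest.fixture(scope="session")
def ha4_noisy():
    truth = ob.preset_truth("ha4", seed=11)
    return truth, ob.simulate_dataset(truth)


@pytest.fixture(scope="session")
def ha4_noisy_fit(ha4_noisy):
    truth, dataset = ha4_noisy
    return truth, dataset, ob.fit_global(dataset, ob.FitOptions(seed=1))


@pytest.fixture()
def coarse_truth():
    """Faster-to-fit variant: 5 s sampling, same rate regime."""
    return ob.preset_truth("ha4", sampling_interval=5.0, seed=21)
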