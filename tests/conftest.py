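import numpy as np
import pandas as pd
import pytest

from ssvepgen import GenParams, fibonacci_net, generate_schedule


@pytest.fixture(scope="session")
def small_net():
    """48-sensor quasi-uniform layout with an 8-sensor occipital pool."""
    return fibonacci_net(48)


@pytest.fixture(scope="session")
def context_schedule():
    """Smallest context-phase schedule: 3 trials per orientation x context."""
    return generate_schedule("context", seed=11, n_per_cell=3)


@pytest.fixture(scope="session")
def acquisition_schedule():
    return generate_schedule("acquisition", seed=11, n_per_cell=3)


@pytest.fixture()
def quiet_params():
    """Low-noise generator parameters for fast, nearly deterministic checks."""
    return GenParams(seed=5, noise_scale=0.5, blink_rate_hz=0.0,
                     pupil_trial_sd_mm=0.0, pupil_noise_sd_mm=0.0)
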