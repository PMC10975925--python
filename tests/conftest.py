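import warnings

import numpy as np
import pytest

from oculopipe import GeneratorConfig, ScreenGeometry, simulate_session


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # drift segments in tiny fixtures legitimately lack 100 fixation samples
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*qualifying fixation samples.*")
        warnings.filterwarnings("ignore", message=".*noise samples for the dynamic.*")
        yield


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return ScreenGeometry(width_px=1280, height_px=1024, width_cm=33.8,
                          height_cm=27.0, distance_cm=60.0)


@pytest.fixture(scope="session")
def small_session():
    """A 30-trial IPAST session with blinks and slosh, plus its ground truth."""
    cfg = GeneratorConfig(n_trials=30, seed=11, blink_rate_per_trial=0.4,
                          slosh_gain=0.5)
    return simulate_session(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
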