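import numpy as np
import pytest

import toddleracc as ta


@pytest.fixture(scope="session")
def params():
    return ta.default_params()


@pytest.fixture(scope="session")
def small_session(params):
    """One simulated participant covering all nine behaviors."""
    bouts = tuple(
        (b, 12.0) for b in ta.PRESCRIBED_BEHAVIORS
    )
    schedule = ta.BoutSchedule("P01", bouts)
    hip, wrist, track = ta.simulate_session(schedule, params, seed=11)
    return hip, wrist, track


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def random_windows(rng):
    """A batch of random 150-sample windows for oracle checks."""
    return [
        ta.SignalWindow("P", "walk", "hip", 5.0 * i, rng.normal(0, 0.5, (150, 3)), 30.0)
        for i in range(6)
    ]
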