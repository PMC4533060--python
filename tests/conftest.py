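import numpy as np
import pytest

from nacclfp import behavior, synthetic_lfp, task_design


@pytest.fixture(scope="session")
def default_design():
    return task_design.generate_design(seed=7)


@pytest.fixture(scope="session")
def small_design():
    """Tiny factorial design for fast unit tests (2 gains x 4 multipliers x 2)."""
    return task_design.generate_design(
        gains=(25.0, 100.0), multipliers=(0.5, 0.8, 1.0, 3.0), repetitions=2, seed=3
    )


@pytest.fixture(scope="session")
def small_trials(small_design):
    params = behavior.DecisionParams(g=30.0, mu=0.1, lam=1.5)
    return behavior.simulate_choices(small_design, 3, params, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_trials):
    """Short 16-trial recording used across preprocessing/spectral tests."""
    cfg = synthetic_lfp.SyntheticConfig(seed=5)
    return synthetic_lfp.synthesize_recording(small_trials, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
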