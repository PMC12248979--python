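import numpy as np
import pytest

from fixfill.synth import GroundTruth, SimConfig, generate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small synthetic experiment with traces, shared across tests.

    Low blink rate so injected events are rarely swallowed by blinks; the
    trial count keeps roughly 100+ injected microsaccades available.
    """
    cfg = SimConfig(n_participants=2, trials_per_block=2, blink_rate=0.0, seed=42)
    trials, traces, truth = generate_experiment(cfg, GroundTruth(), seed=42)
    return cfg, trials, traces, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
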