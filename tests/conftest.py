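import numpy as np
import pytest
from hypothesis import settings

from mrisched.config import ScenarioConfig
from mrisched.twin import DigitalTwin, FailureModel

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_scenario():
    """Short-horizon scenario for fast unit tests."""
    return ScenarioConfig(
        n_machines=3,
        horizon_days=1,
        episode_minutes=240,
        n_seeds=2,
        base_seed=7,
    )


@pytest.fixture
def make_twin():
    """Factory for hand-built twins with explicit arrivals/durations."""

    def build(
        arrivals,
        durations,
        priorities=None,
        n_machines=3,
        p_fail=0.0,
        mean_repair_hours=1.0,
        seed=0,
        round_durations=True,
    ):
        n = len(arrivals)
        if priorities is None:
            priorities = [2] * n
        ss = np.random.SeedSequence(seed)
        s_fail, s_rep = ss.spawn(2)
        return DigitalTwin(
            n_machines=n_machines,
            arrival_times=arrivals,
            durations=durations,
            priorities=priorities,
            failure=FailureModel(p_fail, mean_repair_hours),
            rng_failures=np.random.default_rng(s_fail),
            rng_repairs=np.random.default_rng(s_rep),
            round_durations=round_durations,
        )

    return build
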