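import numpy as np
import pytest
from hypothesis import settings

from cadcea import EngineConfig, GroundTruth, load_default_config

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return load_default_config()


@pytest.fixture
def no_mortality_engine():
    """Engine settings with the background-mortality step switched off."""
    return EngineConfig(mortality_increment=0.0)


@pytest.fixture(scope="session")
def small_truth():
    """A 3-state chain (Well, Sick, Dead) with known dynamics."""
    return GroundTruth(
        states=("Well", "Sick", "Dead"),
        transition_matrix=np.array(
            [[0.8, 0.15, 0.05], [0.1, 0.7, 0.2], [0.0, 0.0, 1.0]]
        ),
        start_distribution=np.array([0.7, 0.3, 0.0]),
        cost_params={"no-intervention": (129.86, 36.06)},
        n_patients=2000,
        n_cycles=10,
        seed=42,
    )


def random_model_matrix(rng, n_states):
    """Row-stochastic matrix whose last state is absorbing (death)."""
    m = rng.dirichlet(np.ones(n_states), size=n_states)
    m[-1] = 0.0
    m[-1, -1] = 1.0
    return m
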