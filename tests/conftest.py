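import numpy as np
import pytest

from morphorsa import (
    SimulationConfig,
    generate_stimulus_set,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort for fast unit tests (4 participants, 2 sessions)."""
    return SimulationConfig(n_participants=4, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_stimset(default_config):
    return generate_stimulus_set(default_config)


def random_rigid(rng: np.random.Generator, reflect: bool | None = None):
    """A random rotation (optionally reflected) and translation in 2D."""
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    if reflect is None:
        reflect = rng.random() < 0.5
    if reflect:
        rot = rot @ np.diag([1.0, -1.0])
    shift = rng.uniform(-20, 20, size=2)
    return rot, shift
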