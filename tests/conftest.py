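import numpy as np
import pytest

from ealpipe import experiment_preset, fixtures


@pytest.fixture(scope="session")
def exp1():
    return experiment_preset(1)


@pytest.fixture(scope="session")
def exp3():
    return experiment_preset(3)


@pytest.fixture(scope="session")
def exp1_noisy20(exp1):
    """A 20-point noisy dataset on informative early times of experiment 1."""
    times = np.tile([1.0, 1.5, 2.0, 3.0], 5)
    return fixtures.make_noisy_dataset(
        exp1.model, exp1.space.truth_vector, times, exp1.noise.sigma, seed=42)
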