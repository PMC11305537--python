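import numpy as np
import pytest

from itspower import ScenarioSpec


@pytest.fixture
def noiseless_scenario():
    """Small deterministic scenario: every score lies on the mean function."""
    return ScenarioSpec(
        n_timepoints=6,
        n_subjects=5,
        effect_size=0.30,
        shape="step_slope",
        baseline_var=0.0,
        noise_var=0.0,
    )


@pytest.fixture
def small_scenario():
    return ScenarioSpec(n_timepoints=8, n_subjects=50, effect_size=0.15)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_301)
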