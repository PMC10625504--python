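import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kinloadclass import synthkin

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_config():
    """The default study design: 12 persons x 80 trials."""
    return synthkin.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def study_trials(study_config):
    return synthkin.generate_dataset(study_config)


@pytest.fixture(scope="session")
def null_trials():
    """Same design with the weight effect switched off (negative control)."""
    return synthkin.generate_dataset(
        synthkin.GeneratorConfig(seed=3, weight_effect=0.0)
    )


@pytest.fixture(scope="session")
def person_dominant_trials():
    """Design with doubled person-level variability (person-dominated)."""
    return synthkin.generate_dataset(
        synthkin.GeneratorConfig(seed=5, person_sd=2.0)
    )


@pytest.fixture
def small_config():
    """A minimal balanced design: 4 persons x 1 block x 8 trials."""
    return synthkin.GeneratorConfig(
        n_persons=4, blocks_per_person=1, trials_per_block=8,
        reps_per_condition=1, seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
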