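import numpy as np
import pytest

from jumppower import GeneratorConfig, build_features, generate_dataset


@pytest.fixture(scope="session")
def small_cohort_dataset():
    """Standard-mode cohort: 6 participants, LB sensor."""
    cfg = GeneratorConfig(n_participants=6, n_holdout=1, seed=42)
    cohort, trials = generate_dataset(cfg, "LB")
    return cfg, cohort, trials


@pytest.fixture(scope="session")
def linear_link_dataset():
    """Linear-link recovery surface: 14 training participants, unit
    observation noise on the target."""
    cfg = GeneratorConfig(
        n_participants=14, n_holdout=0, seed=7, linear_link=True,
        link_noise_sd=1.0, noise_sd=0.02, prob_8_jumps=1.0,
    )
    cohort, trials = generate_dataset(cfg, "LB")
    return cfg, cohort, trials


@pytest.fixture(scope="session")
def linear_link_features(linear_link_dataset):
    _, _, trials = linear_link_dataset
    return build_features(trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
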