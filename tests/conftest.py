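import numpy as np
import pandas as pd
import pytest

from engagenet import (GeneratorConfig, default_ihps_model, sample_survey)


@pytest.fixture(scope="session")
def model():
    return default_ihps_model()


@pytest.fixture(scope="session")
def survey(model):
    """Medium synthetic sample shared across read-only tests."""
    return sample_survey(model, GeneratorConfig(n_respondents=6000, seed=7))


@pytest.fixture(scope="session")
def full_survey(model):
    """Full-cohort sample at the emulated survey size (seed 1)."""
    return sample_survey(model, GeneratorConfig(n_respondents=25_530, seed=1))


def random_counts(rng: np.random.Generator, kx: int, ky: int, kz: int = 1,
                  n: int = 400) -> np.ndarray:
    """Random stratified contingency counts with positive mass."""
    probs = rng.dirichlet(np.ones(kx * ky * kz))
    flat = rng.multinomial(n, probs)
    return flat.reshape(kz, kx, ky)
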