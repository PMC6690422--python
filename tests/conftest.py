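import warnings

import numpy as np
import pandas as pd
import pytest

from densrisk import GeneratorConfig, generate_population

# the range-clamp warning fires whenever a case's age/BMI falls outside the
# control training range; it is expected behaviour, not a test failure
warnings.filterwarnings(
    "ignore", message="prediction input outside training range")


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def study_population(default_config) -> pd.DataFrame:
    """A study-scale sample: 2,243 controls, 474 cases."""
    return generate_population(default_config, seed=101)


@pytest.fixture(scope="session")
def large_population() -> pd.DataFrame:
    """A larger sample for recovery-style checks."""
    cfg = GeneratorConfig(n_controls=8000, n_cases=2000)
    return generate_population(cfg, seed=202)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
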