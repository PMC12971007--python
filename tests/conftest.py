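import numpy as np
import pandas as pd
import pytest

from hemopattern import SimulationConfig, generate_cohort
from hemopattern.cohort import derive_variables


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_subjects=120, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> pd.DataFrame:
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_derived(small_cohort) -> pd.DataFrame:
    return derive_variables(small_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
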