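import numpy as np
import pandas as pd
import pytest

from ubistrat.simulate import SimConfig, simulate_cohort, simulate_expression
from ubistrat.stratify import stratify_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_patients=600, n_genes=400, expr_effect_sd=0.5, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> pd.DataFrame:
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_stratified(small_cohort) -> pd.DataFrame:
    strat, _ = stratify_cohort(small_cohort)
    return strat


@pytest.fixture(scope="session")
def small_expression(small_config, small_cohort) -> pd.DataFrame:
    return simulate_expression(small_config, small_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
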