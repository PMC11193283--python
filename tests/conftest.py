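import numpy as np
import pytest

from yldhale import (
    AbridgedLifeTable,
    PredictorSet,
    SyntheticConfig,
    build_life_table,
    generate_life_table,
    generate_reference_panel,
    load_coefficient_table,
)


@pytest.fixture(scope="session")
def bundled_table():
    return load_coefficient_table("gbd2019_china_3param")


@pytest.fixture(scope="session")
def mean_predictors():
    """The observed mean values of the three indicators, combined sexes."""
    return PredictorSet(iid=0.0023, pcdpf=0.2656, u5mr=0.0289, sex="both")


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=20240622)


@pytest.fixture(scope="session")
def synthetic_panel(default_config):
    return generate_reference_panel(default_config)


@pytest.fixture(scope="session")
def synthetic_lt(default_config):
    return generate_life_table(default_config)


def random_life_table(rng: np.random.Generator) -> AbridgedLifeTable:
    """A valid abridged life table from random but plausible death rates."""
    m = np.exp(rng.uniform(np.log(1e-4), np.log(0.3), size=21))
    m.sort()  # loosely increasing hazard keeps the table human-shaped
    return build_life_table(m)


def random_yld_values(rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.01, 0.6, size=21)
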