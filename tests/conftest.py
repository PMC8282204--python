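import numpy as np
import pytest

from growthmc.design import (
    ICC_SET_1,
    DesignCondition,
    GenerationParams,
    default_variance_components,
)
from growthmc.harness import params_for_condition
from growthmc.simulate import generate_dataset


@pytest.fixture(scope="session")
def icc1_params() -> GenerationParams:
    """Default generating parameters under the low group-level ICC set."""
    return GenerationParams(
        variances=default_variance_components(ICC_SET_1)
    )


@pytest.fixture
def small_condition() -> DesignCondition:
    """A cheap condition for unit tests (not a study-grid cell)."""
    return DesignCondition(
        n_groups=8, group_size_range=(3, 6), icc_spec=ICC_SET_1, base_seed=5
    )


@pytest.fixture
def small_dataset(icc1_params, small_condition):
    return generate_dataset(
        icc1_params.fixed, icc1_params.variances, small_condition, seed=202
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
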