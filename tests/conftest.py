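import numpy as np
import pytest

from hipcea import LifeTable, ModelParams, default_lifetable


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def lifetable() -> LifeTable:
    return default_lifetable()


@pytest.fixture(scope="session")
def zero_mortality_table() -> LifeTable:
    """Background mortality switched off: isolates procedure-driven events."""
    return LifeTable.from_mapping({age: 0.0 for age in range(80, 90)})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
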