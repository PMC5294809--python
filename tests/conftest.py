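import numpy as np
import pytest

from modeljump.model_space import ModelSet


@pytest.fixture(scope="session")
def tstv_set() -> ModelSet:
    return ModelSet.create("tstv_split")


@pytest.fixture(scope="session")
def all_set() -> ModelSet:
    return ModelSet.create("all_reversible")


@pytest.fixture(scope="session")
def named_set() -> ModelSet:
    return ModelSet.create("named")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)
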