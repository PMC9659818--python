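import numpy as np
import pytest

from sarcomech.contractile import CEParameters, MetaboliteState


@pytest.fixture(scope="session")
def params() -> CEParameters:
    return CEParameters()


@pytest.fixture(scope="session")
def metabolites() -> MetaboliteState:
    return MetaboliteState()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)
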