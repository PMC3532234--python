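import numpy as np
import pytest

from rdomarch.io import CategoryMap


@pytest.fixture(scope="session")
def cmap() -> CategoryMap:
    return CategoryMap.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
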