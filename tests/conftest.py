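import numpy as np
import pytest

from yeastcolony import DimensionlessParameters, Grid


@pytest.fixture
def default_params() -> DimensionlessParameters:
    return DimensionlessParameters()


@pytest.fixture
def small_grid() -> Grid:
    return Grid.line(10.0, 0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
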