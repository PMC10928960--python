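import numpy as np
import pytest

from combocal.grid import DoseGrid


@pytest.fixture
def grid33() -> DoseGrid:
    return DoseGrid(3, 3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
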