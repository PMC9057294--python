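import numpy as np
import pytest

from vegdyn.stack import AnnualStack


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_stack(rng):
    """Small 21-year stack of iid noise around 0.5, no nodata."""
    values = np.clip(rng.normal(0.5, 0.1, size=(21, 8, 9)), 0, 1)
    return AnnualStack(values, np.arange(2000, 2021))


@pytest.fixture
def masked_stack(rng):
    """Stack with a few nodata pixels."""
    values = np.clip(rng.normal(0.5, 0.1, size=(10, 6, 6)), 0, 1)
    mask = np.zeros((6, 6), dtype=bool)
    mask[0, 0] = mask[3, 4] = True
    return AnnualStack(values, np.arange(2000, 2010), mask)
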