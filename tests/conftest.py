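import numpy as np
import pytest

from drygene.climate import MonthlyClimate
from drygene.variants import Alignment


@pytest.fixture
def warm_climate():
    """Constant 20 degC, 10 mm/month at the equator."""
    return MonthlyClimate("warm", 0.0, [20.0] * 12, [10.0] * 12)


@pytest.fixture
def toy_alignment():
    """Four 10-bp sequences with two variant columns and one gap."""
    return Alignment(
        gene="toy",
        ids=["s1", "s2", "s3", "s4"],
        sequences=[
            "ACGTACGTAC",
            "ACGTACGTAC",
            "ATGTACGTAC",
            "ATGTACG-AC",
        ],
        taxa=["a", "a", "b", "b"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
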