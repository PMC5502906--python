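import numpy as np
import pytest

from tosteq import Bounds, GroupSummary


@pytest.fixture
def organic_replication():
    """Summary statistics of the organic-food replication (study 2)."""
    control = GroupSummary(n=95, mean=5.25, sd=0.95)
    organic = GroupSummary(n=89, mean=5.22, sd=0.83)
    bounds = Bounds(low=-0.384, high=0.384)
    return control, organic, bounds


@pytest.fixture
def rng():
    return np.random.default_rng(20171948)
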