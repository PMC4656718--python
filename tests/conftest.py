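import numpy as np
import pytest

from csntc.basal_ganglia import BGParams
from csntc.cortex import ReservoirSpec, build_reservoir
from csntc.dynamics import LayerParams


@pytest.fixture(scope="session")
def layer_params():
    return LayerParams()


@pytest.fixture(scope="session")
def bg_params():
    return BGParams()


@pytest.fixture(scope="session")
def small_reservoir():
    """A 60-unit reservoir shared by structural tests."""
    return build_reservoir(ReservoirSpec(n_units=60, n_inputs=2, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
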