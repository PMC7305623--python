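import numpy as np
import pytest

from ncatspipe import lod, simdata
from ncatspipe.simdata import LlrModel, StandardSpec


@pytest.fixture(scope="session")
def standard52():
    """The 897-bp / 52-CpG methylation standard."""
    return simdata.generate_standard(StandardSpec(897, 52, 1.0, seed=7))


@pytest.fixture(scope="session")
def default_model():
    return LlrModel()


@pytest.fixture(scope="session")
def noiseless_model():
    """LLR model with no sign flips and magnitudes far above the cutoff."""
    return LlrModel(mu_meth=10.0, mu_unmeth=10.0, sigma=0.5, miscall_rate=0.0)


@pytest.fixture(scope="session")
def small_pools(standard52, default_model):
    """0% / 100% call pools at modest depth for mixture tests."""
    return lod.simulate_pools(standard52, default_model, pool_depth=60, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
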