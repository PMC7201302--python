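import numpy as np
import pytest

from synsample.encoding import Encoder, EPSPKernel, TuningBank
from synsample.synthdata import Sample, generate_dataset, sample_cluster_params
from synsample.wta import WTAConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clusters():
    return sample_cluster_params(10, seed=7)


@pytest.fixture
def small_encoder():
    """Tiny encoder (20 neurons, 3 features) for fast loop tests."""
    bank = TuningBank.random(20, 3, seed=3)
    return Encoder(bank=bank, kernel=EPSPKernel(), T_ms=200.0, dt_ms=1.0)


@pytest.fixture
def small_wta():
    return WTAConfig(n_outputs=10, R_total_hz=100.0)


@pytest.fixture
def tiny_dataset(clusters):
    return generate_dataset(clusters, 40, seed=9)


@pytest.fixture
def sample3d():
    return Sample(features=np.array([0.2, 0.5, 0.8]), label=4)
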