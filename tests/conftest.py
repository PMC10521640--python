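import numpy as np
import pytest

import ramanres as rr


@pytest.fixture(scope="session")
def sim_cfg_small():
    return rr.SimConfig(n_per_class=25, seed=11)


@pytest.fixture(scope="session")
def small_dataset(sim_cfg_small):
    return rr.simulate_dataset(sim_cfg_small)


@pytest.fixture(scope="session")
def small_matrix(sim_cfg_small, small_dataset):
    dataset, labels = small_dataset
    return rr.preprocess_pipeline(dataset, labels=labels)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    # 64-channel input, 3 stages: large enough to exercise every block kind
    return rr.ModelConfig(
        input_length=64, stem_channels=4, n_stages=3, channel_cap=16,
        dropout_rate=0.1, seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
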