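import numpy as np
import pytest

from adrfusion.fusion import PipelineConfig
from adrfusion.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_config():
    return PipelineConfig.desk_scale()


@pytest.fixture(scope="session")
def tiny_dataset():
    """40 drugs / 8 labels / 12 proteins with a planted signal."""
    return generate_dataset(
        SyntheticConfig(n_drugs=40, n_labels=8, n_proteins=12, seed=7))


@pytest.fixture(scope="session")
def tiny_bundle(tiny_dataset, desk_config):
    from adrfusion.fusion import build_features

    return build_features(tiny_dataset.drugs, tiny_dataset.dp_pairs,
                          tiny_dataset.proteins, desk_config)
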