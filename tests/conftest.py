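import numpy as np
import pytest

from omicsfuse import (
    LayerSpec,
    SNFParams,
    SynthConfig,
    generate_multiomics,
    standardize_layer,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Single clean layer, 40 samples, strong 2-subtype signal."""
    cfg = SynthConfig(
        n_samples=40,
        layer_specs=(LayerSpec("mRNA", 60, 12, 2.0, 1.0, 0.0),),
        seed=11,
    )
    return generate_multiomics(cfg)


@pytest.fixture(scope="session")
def small_layer(small_dataset):
    return standardize_layer(small_dataset.layers[0])


@pytest.fixture(scope="session")
def snf_params():
    return SNFParams(n_neighbors=10, alpha=0.7, iterations=10)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
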