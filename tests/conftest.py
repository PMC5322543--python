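import numpy as np
import pytest

from mirdiverge import GenConfig, generate


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small deterministic synthetic bundle shared across tests."""
    cfg = GenConfig(
        seed=11, n_pairs_wgd=15, n_pairs_td=8, n_triplets=5, n_singletons=10
    )
    out = tmp_path_factory.mktemp("bundle")
    bundle, truth = generate(cfg, out)
    return cfg, bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
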