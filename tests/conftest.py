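import numpy as np
import pytest

import lnrlink as L


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted dataset used by end-to-end checks."""
    return L.generate_dataset(L.PlantedModelConfig(seed=7))


@pytest.fixture(scope="session")
def default_similarities(default_dataset):
    ds = default_dataset
    return (
        L.pcc_similarity(ds.lnc_profiles),
        L.pcc_similarity(ds.mirna_profiles),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
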