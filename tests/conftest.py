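import numpy as np
import pytest

from coverseg import (
    SynthSpec,
    SynthEmbeddingSpec,
    synth_instances,
    synth_embeddings,
    labels_to_affinity,
)


@pytest.fixture(scope="session")
def small_volume():
    """A (16, 64, 64) dense synthetic volume with 5 connected instances."""
    return synth_instances(SynthSpec(shape=(16, 64, 64), n_instances=5, seed=11))


@pytest.fixture(scope="session")
def clustered_embeddings():
    """Six well-separated Gaussian clusters tiling six spatial z-blocks."""
    spec = SynthEmbeddingSpec(seed=3)
    emb, labels = synth_embeddings(spec)
    return spec, emb, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
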