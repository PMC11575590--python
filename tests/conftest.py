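import numpy as np
import pytest

from gammanet.embeddings import EmbeddingCache, HashEmbeddingBackend, embed_component
from gammanet.model import GibbsExcessNet


@pytest.fixture(scope="session")
def backend():
    return HashEmbeddingBackend(dim=16, seed=0)


@pytest.fixture(scope="session")
def cache(backend):
    return EmbeddingCache(backend)


@pytest.fixture(scope="session")
def comp_pair(backend):
    return embed_component("SYN_A", backend), embed_component("SYN_B", backend)


@pytest.fixture
def make_model(backend):
    """Factory for small random-weight models compatible with the session
    backend (D=16)."""

    def _make(seed=0, hidden=8):
        return GibbsExcessNet.create(
            embedding_dim=backend.dim,
            hidden=hidden,
            backend_id=backend.backend_id,
            seed=seed,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
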