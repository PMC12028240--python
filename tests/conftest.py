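import numpy as np
import pytest

from dtialign.embeddings import EmbeddingTable
from dtialign.graph import InteractionGraph
from dtialign.synthetic import SyntheticConfig, generate_world


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_graph():
    """Three proteins, three drugs, one disease; a small multi-layer graph."""
    return InteractionGraph(
        drugs={"D1", "D2", "D3"},
        proteins={"P1", "P2", "P3"},
        diseases={"Z1"},
        dti_edges={("P1", "D1"), ("P1", "D2"), ("P2", "D2"), ("P3", "D3")},
        drug_disease_edges={("D1", "Z1")},
        drug_drug_edges={("D1", "D2")},
    )


@pytest.fixture
def random_table(rng):
    vectors = {f"E{i:03d}": rng.standard_normal(16) for i in range(50)}
    return EmbeddingTable(source="test", dim=16, vectors=vectors)


@pytest.fixture(scope="session")
def small_world():
    """A compact seeded world shared by training/inference tests."""
    return generate_world(
        SyntheticConfig(n_proteins=60, n_drugs=60, latent_dim=4, protein_dim=12, drug_dim=12, seed=5)
    )
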