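import numpy as np
import pytest

from gpdrp.drug_graph import AtomFeatureSchema, smiles_to_graph
from gpdrp.pathway_features import PathwayScoreMatrix

# molecules spanning rings, aromatics, heteroatoms, halogens
FIXTURE_SMILES = [
    "CC",
    "CCO",
    "c1ccccc1",
    "CC(=O)Oc1ccccc1C(=O)O",  # aspirin
    "CN1CCC[C@H]1c1cccnc1",  # nicotine
    "Clc1ccc(Cl)cc1",
    "C1CCOC1",
    "N#Cc1ccccc1",
]


@pytest.fixture(scope="session")
def schema():
    return AtomFeatureSchema()


@pytest.fixture(scope="session")
def fixture_graphs(schema):
    return [smiles_to_graph(s, schema) for s in FIXTURE_SMILES]


@pytest.fixture
def small_scores():
    rng = np.random.default_rng(7)
    return PathwayScoreMatrix(
        values=rng.uniform(-1, 1, size=(6, 5)),
        pathway_ids=[f"PW_{i}" for i in range(6)],
        cell_line_ids=[f"cell_{j}" for j in range(5)],
    )


def random_graph(rng, n_nodes, p_edge=0.5):
    """Random undirected simple graph as an edge list."""
    edges = [
        (i, j)
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]
    return edges
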