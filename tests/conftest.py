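import networkx as nx
import numpy as np
import pytest

from pfasbind.dataset import load_pfas24
from pfasbind.descriptors import descriptor_table
from pfasbind.graph import MolecularGraph


@pytest.fixture(scope="session")
def pfas24():
    return load_pfas24()


@pytest.fixture(scope="session")
def pfas24_descriptors(pfas24):
    df = descriptor_table(pfas24)
    assert df.attrs["failures"] == {}
    return df


def random_molecular_graph(rng: np.random.Generator, max_atoms: int = 12,
                           extra_edge_prob: float = 0.3) -> MolecularGraph:
    """Random connected graph (tree plus a few chords) with random masses."""
    n = int(rng.integers(2, max_atoms + 1))
    tree = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    edges = set(tuple(sorted(e)) for e in tree.edges)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) not in edges and rng.random() < extra_edge_prob / n:
                edges.add((i, j))
    masses = rng.uniform(1.0, 40.0, size=n)
    return MolecularGraph.from_adjacency(sorted(edges), n, masses=masses)
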