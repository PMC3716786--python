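import networkx as nx
import numpy as np
import pytest

from linehap import genotypes as gt


def random_graph(rng: np.random.Generator, n_lo=2, n_hi=8, p=None) -> nx.Graph:
    """Random labeled simple graph (Erdos-Renyi with random density)."""
    n = int(rng.integers(n_lo, n_hi + 1))
    p = float(rng.uniform(0.2, 0.8)) if p is None else p
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < p:
                g.add_edge(u, v)
    return g


def matrix_from_pool(pool: np.ndarray, pairs, ids=None) -> gt.GenotypeMatrix:
    """Genotypes as allele sums of chosen haplotype pairs from a 0/1 pool."""
    calls = np.stack([pool[a] + pool[b] for a, b in pairs]).astype(np.int8)
    ids = ids or [f"g{i}" for i in range(len(pairs))]
    return gt.GenotypeMatrix(ids, [f"s{j}" for j in range(pool.shape[1])], calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def claw():
    return nx.star_graph(3)


@pytest.fixture
def toy_matrix():
    # 4 haplotypes paired into a path of sharings: (0,1),(1,2),(2,3)
    pool = np.array(
        [
            [0, 0, 1, 1, 0, 1],
            [1, 0, 0, 1, 1, 0],
            [0, 1, 1, 0, 0, 0],
            [1, 1, 0, 0, 1, 1],
        ]
    )
    return matrix_from_pool(pool, [(0, 1), (1, 2), (2, 3)]), pool
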