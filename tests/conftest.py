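import itertools

import networkx as nx
import numpy as np
import pytest

from recallnet import SignedNetwork, canonical_fixture
from recallnet.signed_network import normalize_edge


@pytest.fixture(scope="session")
def balanced_fixture() -> SignedNetwork:
    return canonical_fixture("balanced")


@pytest.fixture(scope="session")
def imbalanced_fixture() -> SignedNetwork:
    return canonical_fixture("imbalanced")


def make_net(edges, valences=None, nodes=()) -> SignedNetwork:
    """Build a SignedNetwork from bare pairs, all-positive unless given."""
    valences = valences or {}
    return SignedNetwork.from_edges(
        ((u, v, valences.get(normalize_edge(u, v), 1)) for u, v in edges),
        nodes=nodes,
    )


def census_oracle(net: SignedNetwork) -> tuple[int, int]:
    """Independent brute force: enumerate all C(n,3) node triples and count
    their 2-paths.  Three mutual ties contribute three connected triplets,
    all closed; exactly two ties contribute one open connected triplet."""
    t = t_closed = 0
    for a, b, c in itertools.combinations(sorted(net.nodes), 3):
        n_present = sum(
            1 for u, v in ((a, b), (b, c), (a, c)) if net.has_edge(u, v)
        )
        if n_present == 3:
            t += 3
            t_closed += 3
        elif n_present == 2:
            t += 1
    return t, t_closed


def random_net(seed: int, max_nodes: int = 12) -> SignedNetwork:
    """Random signed graph for oracle cross-checks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.1, 0.9))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    names = [f"N{i:02d}" for i in range(n)]
    return SignedNetwork.from_edges(
        (names[u], names[v], int(rng.choice([1, -1]))) for u, v in g.edges
    )
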