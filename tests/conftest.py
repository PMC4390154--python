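import networkx as nx
import numpy as np
import pytest

from diamonet import Interactome, SeedSet, planted_clique_graph, synthetic_interactome


@pytest.fixture(scope="session")
def triangle() -> Interactome:
    return Interactome.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture(scope="session")
def path4() -> Interactome:
    """Path A - B - C - D."""
    return Interactome.from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture(scope="session")
def clique_net():
    """20-clique embedded in a 500-node / 1000-edge sparse background."""
    return planted_clique_graph(500, 1000, 20, rng_seed=7)


@pytest.fixture(scope="session")
def small_interactome() -> Interactome:
    """Scale-free background, 600 nodes, mean degree ~10."""
    return synthetic_interactome(600, 10.0, rng_seed=11)


def random_net(n: int, p: float, seed: int) -> Interactome:
    G = nx.gnp_random_graph(n, p, seed=seed)
    return Interactome(nx.relabel_nodes(G, {i: f"n{i:03d}" for i in G.nodes}))


def seed_set(genes, name="seeds") -> SeedSet:
    return SeedSet(name, frozenset(genes))
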