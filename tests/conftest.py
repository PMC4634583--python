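"""Shared fixtures: tiny ontologies, networks, and random-instance helpers."""

from __future__ import annotations

import random
from typing import Dict, Tuple

import networkx as nx
import pytest

from mirnetsim import (
    GeneAnnotationMap,
    OntologyGraph,
    WeightedNetwork,
)


@pytest.fixture
def three_node_dag() -> OntologyGraph:
    """Root R with is_a children A and B."""
    return OntologyGraph("BP", [("A", "R", "is_a"), ("B", "R", "is_a")])


@pytest.fixture
def chain_dag() -> OntologyGraph:
    """Chain R <- A <- C, both edges is_a."""
    return OntologyGraph("BP", [("C", "A", "is_a"), ("A", "R", "is_a")])


def make_weighted_net(edges, aspect: str = "BP") -> WeightedNetwork:
    """Weighted network straight from (u, v, weight) triples."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, traversable=w is not None and w > 0)
    return WeightedNetwork(g, aspect)


@pytest.fixture
def single_edge_net() -> WeightedNetwork:
    return make_weighted_net([("g1", "g2", 0.7)])


def random_dag(rng: random.Random, n_terms: int) -> OntologyGraph:
    """Random single-root DAG; each non-root term has 1-2 earlier parents."""
    terms = [f"T{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        k = rng.randint(1, min(2, i))
        for parent in rng.sample(range(i), k):
            relation = "is_a" if rng.random() < 0.7 else "part_of"
            edges.append((terms[i], terms[parent], relation))
    return OntologyGraph("BP", edges, terms)


def random_connected_weighted_net(rng: random.Random, n_nodes: int) -> WeightedNetwork:
    """Connected random graph with edge weights uniform in (0, 1]."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    order = nodes[:]
    rng.shuffle(order)
    for a, b in zip(order, order[1:]):  # random spanning tree
        g.add_edge(a, b)
    extra = rng.randint(0, n_nodes * (n_nodes - 1) // 2 - (n_nodes - 1))
    for _ in range(extra):
        a, b = rng.sample(nodes, 2)
        g.add_edge(a, b)
    for u, v in g.edges():
        w = 1.0 - rng.random()  # uniform in (0, 1]
        g[u][v].update(weight=w, traversable=True)
    return WeightedNetwork(g, "BP")


def brute_force_closure(
    graph: OntologyGraph, term: str, factors: Dict[str, float]
) -> Dict[str, float]:
    """Oracle s-values: explicit enumeration of every root-ward path."""
    best: Dict[str, float] = {term: 1.0}

    def walk(node: str, product: float) -> None:
        for parent, relation in graph.parents(node):
            p = product * factors[relation]
            if p > best.get(parent, 0.0):
                best[parent] = p
            walk(parent, p)  # keep enumerating regardless of the max

    walk(term, 1.0)
    return best


def brute_force_pair_score(
    net: WeightedNetwork, g1: str, g2: str
) -> Tuple[float, object]:
    """Oracle: enumerate all minimum-hop paths, take the max product.

    Products are accumulated from the lexicographically smaller endpoint,
    matching the implementation's canonical direction, so agreement can
    be asserted bit-exactly.
    """
    if g1 == g2:
        return 1.0, 0
    a, b = (g1, g2) if g1 <= g2 else (g2, g1)
    graph = net.traversable_graph
    try:
        paths = list(nx.all_shortest_paths(graph, a, b))
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return 0.0, None
    best = 0.0
    for path in paths:
        product = 1.0
        for u, v in zip(path, path[1:]):
            product *= graph[u][v]["weight"]
        if product > best:
            best = product
    return best, len(paths[0]) - 1
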