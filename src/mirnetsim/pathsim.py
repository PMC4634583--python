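"""Gene-pair functional similarity: best edge-weight product on shortest paths.

The score of a gene pair is the maximum, over all minimum-hop paths
between the two genes in the weighted network, of the product of edge
weights along the path.  "Shortest" means fewest hops; weights only break
ties among equal-hop paths.  The search is a breadth-first traversal with
dominance pruning: at each BFS depth only the best accumulated product
per node is kept, which is sound because all weights lie in (0, 1] and
floating-point multiplication by a positive factor is order-preserving.

A pair of identical genes scores exactly 1; a disconnected pair scores 0.
An optional ``geometric_mean`` rule normalizes the product by the n-th
root, n being the hop count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import WeightedNetwork

_SCORE_RULES = ("product", "geometric_mean")


@dataclass(frozen=True)
class PathSearchConfig:
    """Knobs of the shortest-path scoring.

    max_hops:
        Optional cap on path length; pairs farther apart score 0 and are
        flagged ``capped``.  ``None`` (default) searches unbounded.
    score_rule:
        ``"product"`` (default) scores a path by the plain product of its
        edge weights; ``"geometric_mean"`` takes the n-th root of that
        product, n = hop count.
    """

    max_hops: Optional[int] = None
    score_rule: str = "product"

    def __post_init__(self) -> None:
        if self.max_hops is not None and self.max_hops < 1:
            raise ValueError("max_hops must be >= 1 when set")
        if self.score_rule not in _SCORE_RULES:
            raise ValueError(f"unknown score_rule {self.score_rule!r}")

    def finalize(self, product: float, hops: int) -> float:
        if self.score_rule == "geometric_mean" and hops > 1 and product > 0.0:
            return product ** (1.0 / hops)
        return product


@dataclass
class GenePairScore:
    """Score of one gene pair with the witness path achieving it.

    ``path_length`` is 0 for identical genes and ``None`` for disconnected
    pairs; ``path`` is the lexicographically smallest optimal node
    sequence, making output deterministic.
    """

    gene_i: str
    gene_j: str
    score: float
    path_length: Optional[int]
    path: Optional[Tuple[str, ...]]
    capped: bool = False


def _bfs_levels(
    graph, source: str, limit: Optional[int] = None
) -> Dict[str, int]:
    levels = {source: 0}
    frontier = [source]
    depth = 0
    while frontier and (limit is None or depth < limit):
        depth += 1
        nxt = []
        for u in frontier:
            for v in graph.adj[u]:
                if v not in levels:
                    levels[v] = depth
                    nxt.append(v)
        frontier = nxt
    return levels


def shortest_path_best_product(
    g1: str,
    g2: str,
    net: WeightedNetwork,
    cfg: PathSearchConfig = PathSearchConfig(),
) -> GenePairScore:
    """Best accumulated edge-weight product over minimum-hop paths.

    Raises ``KeyError`` if either gene is absent from the network (the
    set-level aggregation filters such genes out beforehand).
    """
    if g1 not in net:
        raise KeyError(f"gene {g1!r} not in network")
    if g2 not in net:
        raise KeyError(f"gene {g2!r} not in network")
    if g1 == g2:
        return GenePairScore(g1, g2, 1.0, 0, (g1,))
    if g2 < g1:
        # canonical search direction makes score(g1,g2) == score(g2,g1)
        # exact even under floating-point rounding
        rev = shortest_path_best_product(g2, g1, net, cfg)
        return GenePairScore(
            g1,
            g2,
            rev.score,
            rev.path_length,
            tuple(reversed(rev.path)) if rev.path is not None else None,
            rev.capped,
        )
    graph = net.traversable_graph
    dist1 = _bfs_levels(graph, g1, cfg.max_hops)
    if g2 not in dist1:
        capped = cfg.max_hops is not None
        return GenePairScore(g1, g2, 0.0, None, None, capped=capped)
    d = dist1[g2]
    dist2 = _bfs_levels(graph, g2, d)
    # nodes on some minimum-hop path satisfy dist1 + dist2 == d
    frontier: Dict[str, Tuple[float, Tuple[str, ...]]] = {g1: (1.0, (g1,))}
    for depth in range(1, d + 1):
        nxt: Dict[str, Tuple[float, Tuple[str, ...]]] = {}
        for u, (prod, path) in frontier.items():
            for v, data in graph.adj[u].items():
                if dist1.get(v) != depth or dist2.get(v, d + 1) != d - depth:
                    continue
                cand = (prod * data["weight"], path + (v,))
                best = nxt.get(v)
                # dominance pruning: keep the best product per node and
                # depth; break score ties toward the smaller node sequence
                if (
                    best is None
                    or cand[0] > best[0]
                    or (cand[0] == best[0] and cand[1] < best[1])
                ):
                    nxt[v] = cand
        frontier = nxt
    product, path = frontier[g2]
    return GenePairScore(g1, g2, cfg.finalize(product, d), d, path)


def single_source_best_products(
    source: str,
    net: WeightedNetwork,
    cfg: PathSearchConfig = PathSearchConfig(),
) -> Dict[str, Tuple[float, int]]:
    """Raw best products (and hop counts) from *source* to every reachable gene.

    One layered sweep scores all targets at once; results are cached on
    the network (the cache holds raw products, independent of score_rule).
    """
    cache_key = (source, cfg.max_hops)
    cached = net.single_source_cache.get(cache_key)
    if cached is not None:
        return cached
    graph = net.traversable_graph
    if source not in graph:
        raise KeyError(f"gene {source!r} not in network")
    best: Dict[str, Tuple[float, int]] = {source: (1.0, 0)}
    frontier = {source: 1.0}
    depth = 0
    while frontier and (cfg.max_hops is None or depth < cfg.max_hops):
        depth += 1
        nxt: Dict[str, float] = {}
        for u, prod in frontier.items():
            for v, data in graph.adj[u].items():
                if v in best:  # reached at an earlier (shorter) depth
                    continue
                cand = prod * data["weight"]
                if v not in nxt or cand > nxt[v]:
                    nxt[v] = cand
        for v, prod in nxt.items():
            best[v] = (prod, depth)
        frontier = nxt
    net.single_source_cache[cache_key] = best
    return best


def pair_score(
    g1: str,
    g2: str,
    net: WeightedNetwork,
    cfg: PathSearchConfig = PathSearchConfig(),
) -> float:
    """Score only (no witness path), served from the single-source cache."""
    if g1 == g2:
        if g1 not in net:
            raise KeyError(f"gene {g1!r} not in network")
        return 1.0
    source, target = (g1, g2) if g1 <= g2 else (g2, g1)
    hit = net.single_source_cache.get((source, cfg.max_hops))
    if hit is None and (target, cfg.max_hops) in net.single_source_cache:
        source, target = target, source
        hit = net.single_source_cache[(source, cfg.max_hops)]
    if hit is None:
        hit = single_source_best_products(source, net, cfg)
    entry = hit.get(target)
    if entry is None:
        return 0.0
    product, hops = entry
    return cfg.finalize(product, hops)


def all_pairs_gene_scores(
    set1: Sequence[str],
    set2: Sequence[str],
    net: WeightedNetwork,
    cfg: PathSearchConfig = PathSearchConfig(),
) -> pd.DataFrame:
    """|set1| x |set2| matrix of gene-pair scores.

    Both sets must already be restricted to genes present in the network;
    empty inputs yield an empty matrix.
    """
    set1 = list(set1)
    set2 = list(set2)
    values = np.empty((len(set1), len(set2)))
    for i, a in enumerate(set1):
        for j, b in enumerate(set2):
            values[i, j] = pair_score(a, b, net, cfg)
    return pd.DataFrame(values, index=set1, columns=set2)
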