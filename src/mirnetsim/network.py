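"""Integration of PPI edge lists and semantic-similarity edge weighting.

Multiple source edge lists are merged into one non-redundant undirected
protein-protein interaction network (PPIN); each edge is then weighted by
the GO semantic similarity of its endpoint genes, yielding one weighted
network (WPPIN) per GO aspect.  Edges whose weight is missing (either
endpoint unannotated) or zero are retained in the topology but marked
non-traversable, so path search never crosses them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .ontology import (
    DEFAULT_RELATION_FACTORS,
    GeneAnnotationMap,
    OntologyGraph,
    gene_similarity,
)

logger = logging.getLogger(__name__)

_ISOFORM_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(raw: str) -> str:
    """Uppercase a locus id and strip an isoform suffix such as ``.1``."""
    return _ISOFORM_SUFFIX.sub("", raw.strip().upper())


class ProteinNetwork:
    """Undirected, non-redundant PPI network with per-source provenance.

    No self-loops, no duplicate edges; the node set is exactly the union
    of edge endpoints.
    """

    def __init__(self, graph: nx.Graph) -> None:
        self._graph = graph

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._graph.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._graph

    def number_of_edges(self) -> int:
        return self._graph.number_of_edges()

    def number_of_nodes(self) -> int:
        return self._graph.number_of_nodes()

    def edges(self) -> Iterable[Tuple[str, str]]:
        return self._graph.edges()

    def sources(self) -> Tuple[str, ...]:
        names = set()
        for _, _, data in self._graph.edges(data=True):
            names.update(data["sources"])
        return tuple(sorted(names))

    def source_subnetwork(self, name: str) -> "ProteinNetwork":
        """The sub-network contributed by one source database."""
        edges = [
            (u, v)
            for u, v, data in self._graph.edges(data=True)
            if name in data["sources"]
        ]
        sub = nx.Graph()
        sub.add_edges_from(edges)
        return ProteinNetwork(sub)


@dataclass
class TopologySummary:
    """Protein/interaction counts and degree statistics of a network."""

    proteins: int
    interactions: int
    degree_max: int
    degree_min: int
    degree_average: float

    def __post_init__(self) -> None:
        assert self.degree_min >= 1


class WeightedNetwork:
    """A :class:`ProteinNetwork` whose edges carry semantic-similarity weights.

    Every edge stores ``weight`` (float in [0, 1] or ``None`` when the
    similarity is missing) and ``traversable`` (weight strictly positive).
    The traversable subgraph used by path search is cached.
    """

    def __init__(self, graph: nx.Graph, aspect: str) -> None:
        self._graph = graph
        self.aspect = aspect
        self._traversable: Optional[nx.Graph] = None
        # process-wide gene-pair score cache, keyed on the unordered pair
        self.pair_score_cache: Dict[Tuple[str, str], Tuple[float, Optional[int]]] = {}
        self.single_source_cache: Dict[str, Dict[str, Tuple[float, int]]] = {}

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    def __contains__(self, gene: str) -> bool:
        return gene in self._graph

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._graph.nodes)

    def edge_weight(self, u: str, v: str) -> Optional[float]:
        return self._graph[u][v]["weight"]

    @property
    def traversable_graph(self) -> nx.Graph:
        if self._traversable is None:
            g = nx.Graph()
            g.add_nodes_from(self._graph.nodes)
            for u, v, data in self._graph.edges(data=True):
                if data["traversable"]:
                    g.add_edge(u, v, weight=data["weight"])
            self._traversable = g
        return self._traversable

    def counts(self) -> Dict[str, int]:
        retained = sum(
            1 for _, _, d in self._graph.edges(data=True) if d["traversable"]
        )
        total = self._graph.number_of_edges()
        return {"retained": retained, "dropped": total - retained, "total": total}

    # -- serialization -------------------------------------------------

    def to_tsv(self, path: str, precision: int = 6) -> None:
        """Write a 3-column (gene, gene, weight) TSV; missing weight as NA."""
        with open(path, "w") as out:
            for u, v in sorted(map(sorted, self._graph.edges())):
                w = self._graph[u][v]["weight"]
                text = "NA" if w is None else f"{w:.{precision}f}"
                out.write(f"{u}\t{v}\t{text}\n")

    @classmethod
    def from_tsv(cls, path: str, aspect: str = "BP") -> "WeightedNetwork":
        g = nx.Graph()
        with open(path) as handle:
            for line in handle:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 3:
                    raise ValueError(f"weighted network line has <3 columns: {line!r}")
                u, v, text = cols[0], cols[1], cols[2]
                weight = None if text == "NA" else float(text)
                g.add_edge(u, v, weight=weight, traversable=bool(weight))
        return cls(g, aspect)


def read_edge_list(path: str) -> List[Tuple[str, str]]:
    """Read a tab-separated 2-column edge list (``#`` comments allowed)."""
    edges = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"edge list line has <2 columns: {line!r}")
            edges.append((cols[0], cols[1]))
    return edges


def read_mitab(path: str) -> List[Tuple[str, str]]:
    """Extract interactor identifiers from columns 1-2 of a PSI-MITAB 2.5 file.

    Identifiers of the form ``db:accession`` are reduced to the accession.
    """
    edges = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"MITAB line has <2 columns: {line!r}")
            a = cols[0].split("|")[0].split(":")[-1]
            b = cols[1].split("|")[0].split(":")[-1]
            edges.append((a, b))
    return edges


def integrate_edge_lists(
    sources: Mapping[str, Sequence[Tuple[str, str]]] | Sequence[Sequence[Tuple[str, str]]],
    normalize: bool = True,
) -> ProteinNetwork:
    """Union several edge lists into one non-redundant undirected network.

    ``(a, b)`` and ``(b, a)`` collapse to one edge; self-loops are
    dropped; each edge remembers which sources contributed it.  Raises if
    the union is empty.
    """
    if not isinstance(sources, Mapping):
        sources = {f"source{i + 1}": edges for i, edges in enumerate(sources)}
    g = nx.Graph()
    for name, edges in sources.items():
        for a, b in edges:
            if normalize:
                a, b = normalize_gene_id(a), normalize_gene_id(b)
            if a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["sources"].add(name)
            else:
                g.add_edge(a, b, sources={name})
    if g.number_of_edges() == 0:
        raise ValueError("edge-list union is empty (only self-loops or no input)")
    return ProteinNetwork(g)


def weight_network(
    net: ProteinNetwork,
    annotations: GeneAnnotationMap,
    graph: OntologyGraph,
    combine: str = "bma",
    relation_factors: Mapping[str, float] = DEFAULT_RELATION_FACTORS,
    epsilon_floor: Optional[float] = None,
) -> WeightedNetwork:
    """Weight every PPIN edge with the endpoint genes' semantic similarity.

    Edges with missing or zero similarity become non-traversable unless
    *epsilon_floor* is given, in which case they are floored to that value
    and kept traversable.
    """
    wg = nx.Graph()
    wg.add_nodes_from(net.graph.nodes)
    sim_cache: Dict[Tuple[str, str], Optional[float]] = {}
    for u, v, data in net.graph.edges(data=True):
        key = (u, v) if u <= v else (v, u)
        if key in sim_cache:
            sim = sim_cache[key]
        else:
            sim = gene_similarity(u, v, annotations, graph, combine, relation_factors)
            sim_cache[key] = sim
        if (sim is None or sim <= 0.0) and epsilon_floor is not None:
            sim = epsilon_floor
        traversable = sim is not None and sim > 0.0
        wg.add_edge(u, v, weight=sim, traversable=traversable, sources=data.get("sources"))
    weighted = WeightedNetwork(wg, graph.aspect)
    counts = weighted.counts()
    if counts["retained"] == 0:
        logger.warning(
            "no traversable edges: all %d edge weights are missing or zero",
            counts["total"],
        )
    return weighted


def topology_summary(net: ProteinNetwork | nx.Graph) -> TopologySummary:
    """Protein count, interaction count and degree max/min/average.

    The average degree is ``2 * interactions / proteins``, reported to two
    decimals.  Raises on an empty network.
    """
    g = net.graph if isinstance(net, ProteinNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("cannot summarize an empty network")
    degrees = [d for _, d in g.degree()]
    n, m = g.number_of_nodes(), g.number_of_edges()
    return TopologySummary(
        proteins=n,
        interactions=m,
        degree_max=max(degrees),
        degree_min=min(degrees),
        degree_average=round(2 * m / n, 2),
    )
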