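"""Gene Ontology parsing and graph-based (Wang-style) semantic similarity.

The similarity of two GO terms is computed from their ancestor closures:
every ancestor of a term contributes an *s-value*, defined recursively as
the best product of relation contribution factors along any path from the
focal term up to that ancestor (``s = 1`` for the focal term itself).  The
similarity of two terms is the summed s-value overlap of their closures
normalised by the two semantic values (closure sums).  Gene-level
similarity aggregates the term-term matrix with a best-match average (BMA)
or a plain maximum.

Only ``is_a`` and ``part_of`` edges participate; other relation kinds are
skipped at parse time.  Each of the three orthogonal ontologies (BP, CC,
MF) is held as its own DAG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Tuple

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: default contribution factors of the graph-based similarity measure
DEFAULT_RELATION_FACTORS: Mapping[str, float] = {"is_a": 0.8, "part_of": 0.6}

ASPECTS = ("BP", "CC", "MF")

_NAMESPACE_TO_ASPECT = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}

_ALLOWED_RELATIONS = frozenset({"is_a", "part_of"})


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, unknown terms)."""


@dataclass
class TermAncestorClosure:
    """Ancestor closure of one term with its per-ancestor s-values.

    ``s_values`` maps every member (the focal term plus all its ancestors)
    to its contribution score in (0, 1]; ``semantic_value`` is their sum.
    """

    focal: str
    s_values: Dict[str, float]
    semantic_value: float

    @property
    def members(self) -> FrozenSet[str]:
        return frozenset(self.s_values)


class OntologyGraph:
    """One GO aspect as a DAG of child -> parent relations.

    Parameters
    ----------
    aspect:
        One of ``"BP"``, ``"CC"``, ``"MF"``.
    edges:
        Iterable of ``(child, parent, relation)`` triples with relation in
        ``{"is_a", "part_of"}``.
    terms:
        Optional explicit term set; defaults to the union of edge endpoints.
    """

    def __init__(
        self,
        aspect: str,
        edges: Iterable[Tuple[str, str, str]],
        terms: Optional[Iterable[str]] = None,
    ) -> None:
        if aspect not in ASPECTS:
            raise ValueError(f"unknown aspect {aspect!r}; expected one of {ASPECTS}")
        self.aspect = aspect
        g = nx.MultiDiGraph()
        if terms is not None:
            g.add_nodes_from(terms)
        for child, parent, relation in edges:
            if relation not in _ALLOWED_RELATIONS:
                raise OntologyError(f"unsupported relation kind {relation!r}")
            g.add_edge(child, parent, key=relation)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology relations contain a cycle: {cycle}")
        self._graph = g
        # caches keyed by (term, factors) resp. (pair, factors)
        self._closure_cache: Dict[Tuple, TermAncestorClosure] = {}
        self._sim_cache: Dict[Tuple, float] = {}

    # -- basic queries -------------------------------------------------

    @property
    def terms(self) -> FrozenSet[str]:
        return frozenset(self._graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def parents(self, term: str) -> Iterable[Tuple[str, str]]:
        """Yield ``(parent, relation)`` for the given term."""
        for _, parent, relation in self._graph.out_edges(term, keys=True):
            yield parent, relation

    def ancestors(self, term: str) -> FrozenSet[str]:
        """All terms reachable by following child -> parent edges."""
        return frozenset(nx.descendants(self._graph, term))

    # -- semantic similarity ------------------------------------------

    def closure(
        self,
        term: str,
        relation_factors: Mapping[str, float] = DEFAULT_RELATION_FACTORS,
    ) -> TermAncestorClosure:
        """Ancestor closure of *term* with dynamic-programming s-values.

        The s-value of a closure member is the maximum, over its children
        inside the closure, of the child's s-value times the relation's
        contribution factor; the focal term has s-value 1.
        """
        if term not in self._graph:
            raise OntologyError(f"term {term!r} not in {self.aspect} ontology")
        key = (term, tuple(sorted(relation_factors.items())))
        cached = self._closure_cache.get(key)
        if cached is not None:
            return cached
        members = set(nx.descendants(self._graph, term))
        members.add(term)
        sub = self._graph.subgraph(members)
        s: Dict[str, float] = {term: 1.0}
        # edges run child -> parent, so a topological order visits every
        # child before its parents
        for node in nx.topological_sort(sub):
            if node == term:
                continue
            best = 0.0
            for child, _, relation in sub.in_edges(node, keys=True):
                factor = relation_factors[relation]
                cand = factor * s[child]
                if cand > best:
                    best = cand
            s[node] = best
        closure = TermAncestorClosure(
            focal=term, s_values=s, semantic_value=sum(s.values())
        )
        self._closure_cache[key] = closure
        return closure

    def term_similarity(
        self,
        a: str,
        b: str,
        relation_factors: Mapping[str, float] = DEFAULT_RELATION_FACTORS,
    ) -> float:
        """Graph-based semantic similarity of two terms, in (0, 1].

        Equals 1 for identical terms; symmetric; always positive within an
        aspect because both closures contain the aspect root.
        """
        if a == b:
            if a not in self._graph:
                raise OntologyError(f"term {a!r} not in {self.aspect} ontology")
            return 1.0
        fkey = tuple(sorted(relation_factors.items()))
        key = (min(a, b), max(a, b), fkey)
        cached = self._sim_cache.get(key)
        if cached is not None:
            return cached
        ca = self.closure(a, relation_factors)
        cb = self.closure(b, relation_factors)
        common = ca.members & cb.members
        overlap = sum(ca.s_values[t] + cb.s_values[t] for t in common)
        sim = overlap / (ca.semantic_value + cb.semantic_value)
        self._sim_cache[key] = sim
        return sim


@dataclass
class GeneAnnotationMap:
    """Per-aspect gene -> GO-term annotations.

    ``evidence_excluded`` records which evidence codes were filtered out at
    load time (recorded for provenance, not re-enforced here).
    """

    by_aspect: Dict[str, Dict[str, FrozenSet[str]]]
    evidence_excluded: Tuple[str, ...] = ()

    def terms(self, gene: str, aspect: str) -> FrozenSet[str]:
        return self.by_aspect.get(aspect, {}).get(gene, frozenset())

    def is_annotated(self, gene: str, aspect: str) -> bool:
        return bool(self.terms(gene, aspect))

    def genes(self, aspect: str) -> FrozenSet[str]:
        return frozenset(self.by_aspect.get(aspect, {}))

    def validate_against(self, ontologies: Mapping[str, OntologyGraph]) -> None:
        """Drop annotation terms absent from the aspect's ontology.

        Unknown terms are counted and logged; genes left with no terms in
        an aspect are removed from that aspect's map (they then report as
        unannotated).
        """
        for aspect, gene_map in self.by_aspect.items():
            graph = ontologies.get(aspect)
            if graph is None:
                continue
            dropped = 0
            for gene in list(gene_map):
                known = frozenset(t for t in gene_map[gene] if t in graph)
                dropped += len(gene_map[gene]) - len(known)
                if known:
                    gene_map[gene] = known
                else:
                    del gene_map[gene]
            if dropped:
                logger.warning(
                    "dropped %d annotation(s) with terms unknown to the %s ontology",
                    dropped,
                    aspect,
                )


def load_obo(path: str) -> Dict[str, OntologyGraph]:
    """Parse an OBO 1.2/1.4 file into one :class:`OntologyGraph` per aspect.

    Obsolete terms are dropped (the parser skips them), only ``is_a`` and
    ``part_of`` edges are retained, and a count of skipped edges of other
    relation kinds is logged.  Raises :class:`OntologyError` on cyclic
    relations.
    """
    raw = obonet.read_obo(path, ignore_obsolete=True)
    per_aspect_edges: Dict[str, list] = {a: [] for a in ASPECTS}
    per_aspect_terms: Dict[str, set] = {a: set() for a in ASPECTS}
    skipped = 0
    aspect_of: Dict[str, str] = {}
    for term, data in raw.nodes(data=True):
        namespace = data.get("namespace")
        aspect = _NAMESPACE_TO_ASPECT.get(namespace)
        if aspect is None:
            logger.warning("term %s has unknown namespace %r; skipped", term, namespace)
            continue
        aspect_of[term] = aspect
        per_aspect_terms[aspect].add(term)
    # obonet edges run child -> parent with the relation as the key
    for child, parent, relation in raw.edges(keys=True):
        if relation not in _ALLOWED_RELATIONS:
            skipped += 1
            continue
        aspect = aspect_of.get(child)
        if aspect is None or aspect_of.get(parent) != aspect:
            continue
        per_aspect_edges[aspect].append((child, parent, relation))
    if skipped:
        logger.info("skipped %d edge(s) with unsupported relation kinds", skipped)
    return {
        aspect: OntologyGraph(aspect, per_aspect_edges[aspect], per_aspect_terms[aspect])
        for aspect in ASPECTS
        if per_aspect_terms[aspect]
    }


_GAF_ASPECT = {"P": "BP", "C": "CC", "F": "MF"}


def load_gaf(
    path: str,
    exclude_evidence: Iterable[str] = (),
    ontologies: Optional[Mapping[str, OntologyGraph]] = None,
) -> GeneAnnotationMap:
    """Read a GAF 2.x annotation file.

    Uses DB Object ID (column 2), GO ID (column 5), evidence code
    (column 7) and aspect (column 9).  Evidence codes listed in
    *exclude_evidence* are dropped; by default nothing is filtered.
    """
    exclude = frozenset(exclude_evidence)
    by_aspect: Dict[str, Dict[str, set]] = {a: {} for a in ASPECTS}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GAF line (<9 columns): {line!r}")
            gene, term, evidence, aspect_code = cols[1], cols[4], cols[6], cols[8]
            if evidence in exclude:
                continue
            aspect = _GAF_ASPECT.get(aspect_code)
            if aspect is None:
                raise ValueError(f"unknown GAF aspect code {aspect_code!r}")
            by_aspect[aspect].setdefault(gene, set()).add(term)
    amap = GeneAnnotationMap(
        by_aspect={a: {g: frozenset(t) for g, t in m.items()} for a, m in by_aspect.items()},
        evidence_excluded=tuple(sorted(exclude)),
    )
    if ontologies is not None:
        amap.validate_against(ontologies)
    return amap


def load_annotation_table(
    path: str,
    aspect: str,
    ontologies: Optional[Mapping[str, OntologyGraph]] = None,
) -> GeneAnnotationMap:
    """Read a plain two-column (gene, term) TSV for a single aspect."""
    if aspect not in ASPECTS:
        raise ValueError(f"unknown aspect {aspect!r}")
    gene_map: Dict[str, set] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"annotation table line has <2 columns: {line!r}")
            gene_map.setdefault(cols[0], set()).add(cols[1])
    amap = GeneAnnotationMap(
        by_aspect={aspect: {g: frozenset(t) for g, t in gene_map.items()}}
    )
    if ontologies is not None:
        amap.validate_against(ontologies)
    return amap


def gene_similarity(
    g1: str,
    g2: str,
    annotations: GeneAnnotationMap,
    graph: OntologyGraph,
    combine: str = "bma",
    relation_factors: Mapping[str, float] = DEFAULT_RELATION_FACTORS,
) -> Optional[float]:
    """Semantic similarity of two genes within one aspect.

    Returns ``None`` ("missing") when either gene carries no annotation in
    the aspect — deliberately distinct from 0, so downstream network
    weighting can exclude rather than zero such edges.  With
    ``combine="bma"`` the term matrix is aggregated as
    ``(sum of row maxima + sum of column maxima) / (m + n)``; with
    ``combine="max"`` the single best term pair is returned.
    """
    if combine not in ("bma", "max"):
        raise ValueError(f"unknown combine rule {combine!r}")
    t1 = annotations.terms(g1, graph.aspect)
    t2 = annotations.terms(g2, graph.aspect)
    if not t1 or not t2:
        return None
    if g1 == g2:
        return 1.0
    rows = sorted(t1)
    cols = sorted(t2)
    matrix = [
        [graph.term_similarity(a, b, relation_factors) for b in cols] for a in rows
    ]
    if combine == "max":
        return max(max(row) for row in matrix)
    row_max = sum(max(row) for row in matrix)
    col_max = sum(max(matrix[i][j] for i in range(len(rows))) for j in range(len(cols)))
    return (row_max + col_max) / (len(rows) + len(cols))
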