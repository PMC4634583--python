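"""Self-contained synthetic fixtures for every pipeline stage.

Generates toy GO DAGs, gene annotations, PPI edge lists, miRNA target
sets, family labels, genome coordinates and stress associations with
controllable effect sizes, so the whole pipeline is testable without any
external download.

The designed similarity gradient works as follows: each miRNA family (or
stress group) owns a shared target-gene pool covering a declared fraction
(the *effect*) of its members' targets; pool genes are wired into a
planted clique and annotated with a common deep GO term, so both the
network topology and the edge weights carry the signal.  With effect 0
the pools are empty and intra-group miRNAs are statistically
indistinguishable from random ones — the calibration null.

Generation is a pure function of the spec (same seed, byte-identical
files); the genomic layout places planted cluster members within the
10-kb chaining distance and everything else far apart.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import ProteinNetwork, integrate_edge_lists
from .ontology import ASPECTS, GeneAnnotationMap, OntologyGraph
from .setsim import TargetGeneSet

_ASPECT_NAMESPACE = {
    "BP": "biological_process",
    "CC": "cellular_component",
    "MF": "molecular_function",
}
_ASPECT_CODE = {"BP": "P", "CC": "C", "MF": "F"}
_ASPECT_OFFSET = {"BP": 1_000_000, "CC": 2_000_000, "MF": 3_000_000}

#: stress vocabulary: 12 abiotic plus 3 biotic kinds
STRESS_VOCABULARY: Tuple[str, ...] = (
    "drought",
    "salinity",
    "cold",
    "heat",
    "oxidative",
    "uv",
    "aba",
    "hypoxia",
    "osmotic",
    "wounding",
    "nutrient_deficiency",
    "heavy_metal",
    "bacteria",
    "fungi",
    "virus",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults emulate a desk-scale plant system: small target sets
    (plant miRNAs average roughly eight targets each), a sparse but
    connected interactome, and shallow GO DAGs with one root per aspect.
    """

    # ontology (per aspect)
    n_terms: int = 40
    max_depth: int = 4
    part_of_fraction: float = 0.2
    # annotations
    terms_per_gene: Tuple[int, int] = (2, 4)
    # network
    n_genes: int = 80
    edge_prob: float = 0.05
    # miRNAs and effects
    n_families: int = 10
    family_size: int = 4
    n_free_mirnas: int = 20
    targets_per_mirna: Tuple[int, int] = (5, 10)
    family_effect: float = 0.75
    n_stress_groups: int = 3
    stress_group_size: int = 5
    stress_effect: float = 0.75
    n_genomic_clusters: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_terms",
            "max_depth",
            "n_genes",
            "n_families",
            "family_size",
            "n_free_mirnas",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("part_of_fraction", "family_effect", "stress_effect", "edge_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        lo, hi = self.targets_per_mirna
        if not 1 <= lo <= hi:
            raise ValueError("targets_per_mirna must be an increasing positive range")
        if hi > self.n_genes:
            raise ValueError("more targets per miRNA than genes available")
        if self.n_stress_groups * self.stress_group_size > self.n_free_mirnas:
            raise ValueError("stress groups do not fit into the free miRNA pool")
        if self.n_genomic_clusters > self.n_families:
            raise ValueError("cannot plant more genomic clusters than families")

    @property
    def n_mirnas(self) -> int:
        return self.n_families * self.family_size + self.n_free_mirnas


@dataclass
class SyntheticData:
    """In-memory bundle mirroring the on-disk fixture files."""

    spec: FixtureSpec
    ontologies: Dict[str, OntologyGraph]
    annotations: GeneAnnotationMap
    network: ProteinNetwork
    edge_sources: Dict[str, List[Tuple[str, str]]]
    target_sets: Dict[str, TargetGeneSet]
    families: Dict[str, str]
    coordinates: pd.DataFrame
    stress: Dict[str, FrozenSet[str]]
    # raw annotation rows (gene, term, aspect) for the GAF writer
    annotation_rows: List[Tuple[str, str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# generation


def _generate_ontology(
    aspect: str, spec: FixtureSpec, rng: np.random.Generator
) -> Tuple[OntologyGraph, List[Tuple[str, str, str]], List[str]]:
    """Layered random DAG with a single root; every term reaches the root."""
    offset = _ASPECT_OFFSET[aspect]
    ids = [f"GO:{offset + i:07d}" for i in range(spec.n_terms)]
    root = ids[0]
    depth_of = {root: 0}
    # spread non-root terms over depths 1..max_depth (deeper layers exist
    # only once the shallower ones are populated)
    layers: Dict[int, List[str]] = {0: [root]}
    for i, term in enumerate(ids[1:]):
        depth = min(1 + i % spec.max_depth, spec.max_depth)
        while depth > 1 and not layers.get(depth - 1):
            depth -= 1
        layers.setdefault(depth, []).append(term)
        depth_of[term] = depth
    edges: List[Tuple[str, str, str]] = []
    for depth in sorted(layers):
        if depth == 0:
            continue
        for term in layers[depth]:
            parents_pool = layers[depth - 1]
            k = int(rng.integers(1, min(2, len(parents_pool)) + 1))
            parents = rng.choice(len(parents_pool), size=k, replace=False)
            for p in sorted(parents):
                relation = (
                    "part_of"
                    if rng.random() < spec.part_of_fraction
                    else "is_a"
                )
                edges.append((term, parents_pool[p], relation))
    deepest = layers[max(layers)]
    return OntologyGraph(aspect, edges, ids), edges, deepest


def _draw_targets(
    rng: np.random.Generator,
    genes: Sequence[str],
    count: int,
    pool: Sequence[str] = (),
) -> FrozenSet[str]:
    chosen = set(pool)
    remaining = [g for g in genes if g not in chosen]
    extra = min(count, len(remaining))
    if extra:
        picks = rng.choice(len(remaining), size=extra, replace=False)
        chosen.update(remaining[i] for i in picks)
    return frozenset(chosen)


def generate_dataset(spec: FixtureSpec) -> SyntheticData:
    """Build the full synthetic bundle in memory (pure function of *spec*)."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:03d}" for i in range(spec.n_genes)]

    # ontologies and per-group focal terms
    ontologies: Dict[str, OntologyGraph] = {}
    deep_terms: Dict[str, List[str]] = {}
    obo_edges: Dict[str, List[Tuple[str, str, str]]] = {}
    for aspect in ASPECTS:
        graph, edges, deepest = _generate_ontology(aspect, spec, rng)
        ontologies[aspect] = graph
        obo_edges[aspect] = edges
        deep_terms[aspect] = deepest

    # miRNA identities and family labels
    mirnas: List[str] = [f"miR{i + 1:03d}" for i in range(spec.n_mirnas)]
    families: Dict[str, str] = {}
    family_members: List[List[str]] = []
    cursor = 0
    for f in range(spec.n_families):
        members = mirnas[cursor : cursor + spec.family_size]
        cursor += spec.family_size
        family_members.append(members)
        for m in members:
            families[m] = f"FAM{f + 1:02d}"
    free = mirnas[cursor:]

    # stress groups drawn from the free miRNAs
    stress: Dict[str, FrozenSet[str]] = {}
    stress_groups: List[Tuple[str, List[str]]] = []
    labels = list(STRESS_VOCABULARY)
    for s in range(spec.n_stress_groups):
        members = free[s * spec.stress_group_size : (s + 1) * spec.stress_group_size]
        label = labels[s % len(labels)]
        stress_groups.append((label, members))
        for m in members:
            stress[m] = frozenset({label})

    # target sets: shared pools sized by the effect, private remainder
    lo, hi = spec.targets_per_mirna
    target_sets: Dict[str, TargetGeneSet] = {}
    pools: List[List[str]] = []

    def _assign_group(members: Sequence[str], effect: float) -> None:
        k_group = int(rng.integers(lo, hi + 1))
        pool_size = int(round(effect * k_group))
        if pool_size > spec.n_genes:
            raise ValueError("shared target pool larger than the gene universe")
        pool_idx = rng.choice(spec.n_genes, size=pool_size, replace=False)
        pool = [genes[i] for i in sorted(pool_idx)]
        if len(pool) >= 2:
            pools.append(pool)
        for m in members:
            k = int(rng.integers(lo, hi + 1))
            private = int(round((1.0 - effect) * k))
            target_sets[m] = TargetGeneSet(m, _draw_targets(rng, genes, private, pool))

    for members in family_members:
        _assign_group(members, spec.family_effect)
    for _, members in stress_groups:
        _assign_group(members, spec.stress_effect)
    for m in free[spec.n_stress_groups * spec.stress_group_size :]:
        k = int(rng.integers(lo, hi + 1))
        target_sets[m] = TargetGeneSet(m, _draw_targets(rng, genes, k))

    # network: Erdos-Renyi core, connected, plus planted pool cliques
    edge_set = set()
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            if rng.random() < spec.edge_prob:
                edge_set.add((genes[i], genes[j]))
    # stitch components together so path search always has a route
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from(edge_set)
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: c[0])
    for prev, comp in zip(components, components[1:]):
        a = prev[int(rng.integers(len(prev)))]
        b = comp[int(rng.integers(len(comp)))]
        edge_set.add((min(a, b), max(a, b)))
    clique_edges = set()
    for pool in pools:
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                e = (pool[i], pool[j])
                if e not in edge_set:
                    clique_edges.add(e)
    all_edges = sorted(edge_set | clique_edges)
    # two overlapping source databases (deterministic split with overlap)
    source_a = [e for i, e in enumerate(all_edges) if i % 3 != 2]
    source_b = [e for i, e in enumerate(all_edges) if i % 3 != 0]
    edge_sources = {"dbA": source_a, "dbB": source_b}
    network = integrate_edge_lists(edge_sources, normalize=False)

    # annotations: random terms, plus one shared deep focal term per pool
    focal: Dict[Tuple[str, int], str] = {}
    pool_of_gene: Dict[str, int] = {}
    for p, pool in enumerate(pools):
        for aspect in ASPECTS:
            deepest = deep_terms[aspect]
            focal[(aspect, p)] = deepest[p % len(deepest)]
        for gene in pool:
            pool_of_gene.setdefault(gene, p)
    tlo, thi = spec.terms_per_gene
    by_aspect: Dict[str, Dict[str, FrozenSet[str]]] = {a: {} for a in ASPECTS}
    rows: List[Tuple[str, str, str]] = []
    all_terms = {a: sorted(ontologies[a].terms) for a in ASPECTS}
    for gene in genes:
        for aspect in ASPECTS:
            k = int(rng.integers(tlo, thi + 1))
            terms = set()
            p = pool_of_gene.get(gene)
            if p is not None:
                terms.add(focal[(aspect, p)])
            candidates = all_terms[aspect]
            while len(terms) < k:
                terms.add(candidates[int(rng.integers(len(candidates)))])
            by_aspect[aspect][gene] = frozenset(terms)
            for t in sorted(terms):
                rows.append((gene, t, aspect))
    annotations = GeneAnnotationMap(by_aspect)

    # genome coordinates: planted clusters adjacent, everything else sparse
    cluster_units: List[List[str]] = [
        family_members[c] for c in range(spec.n_genomic_clusters)
    ]
    clustered = {m for unit in cluster_units for m in unit}
    units: List[List[str]] = list(cluster_units) + [
        [m] for m in mirnas if m not in clustered
    ]
    order = rng.permutation(len(units))
    chroms = [f"Chr{i + 1}" for i in range(5)]
    cursor_pos = {c: 0 for c in chroms}
    records = []
    for rank, u in enumerate(order):
        unit = units[u]
        chrom = chroms[rank % len(chroms)]
        pos = cursor_pos[chrom] + int(rng.integers(20_000, 100_000))
        for m in unit:
            length = int(rng.integers(80, 201))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append((m, chrom, pos, pos + length - 1, strand))
            pos = pos + length - 1 + int(rng.integers(200, 8_000))
        cursor_pos[chrom] = pos + 20_000
    coordinates = pd.DataFrame(
        records, columns=["mirna", "chrom", "start", "end", "strand"]
    )

    return SyntheticData(
        spec=spec,
        ontologies=ontologies,
        annotations=annotations,
        network=network,
        edge_sources=edge_sources,
        target_sets=target_sets,
        families=families,
        coordinates=coordinates,
        stress=stress,
        annotation_rows=rows,
    )


# ---------------------------------------------------------------------------
# file writers (dialects match the corresponding readers)


def _write_obo(data: SyntheticData, path: str) -> None:
    with open(path, "w") as out:
        out.write("format-version: 1.2\n")
        out.write("ontology: synthetic-go\n")
        for aspect in ASPECTS:
            graph = data.ontologies[aspect]
            parents: Dict[str, List[Tuple[str, str]]] = {}
            for child, parent, relation in _iter_edges(graph):
                parents.setdefault(child, []).append((parent, relation))
            for term in sorted(graph.terms):
                out.write("\n[Term]\n")
                out.write(f"id: {term}\n")
                out.write(f"name: synthetic term {term[3:]}\n")
                out.write(f"namespace: {_ASPECT_NAMESPACE[aspect]}\n")
                for parent, relation in sorted(parents.get(term, [])):
                    if relation == "is_a":
                        out.write(f"is_a: {parent}\n")
                    else:
                        out.write(f"relationship: part_of {parent}\n")


def _iter_edges(graph: OntologyGraph):
    for term in sorted(graph.terms):
        for parent, relation in graph.parents(term):
            yield term, parent, relation


def _write_gaf(data: SyntheticData, path: str) -> None:
    with open(path, "w") as out:
        out.write("!gaf-version: 2.2\n")
        for gene, term, aspect in sorted(data.annotation_rows):
            cols = [
                "SYNT",
                gene,
                gene,
                "enables",
                term,
                "SYNT_REF:0000001",
                "IDA",
                "",
                _ASPECT_CODE[aspect],
                "",
                "",
                "protein",
                "taxon:3702",
                "20260101",
                "SYNT",
                "",
                "",
            ]
            out.write("\t".join(cols) + "\n")


def generate_fixture(spec: FixtureSpec, outdir: str) -> Dict[str, str]:
    """Write the full fixture bundle to *outdir* and return the file paths.

    Regeneration under the same spec (seed included) is byte-identical.
    """
    data = generate_dataset(spec)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "obo": os.path.join(outdir, "ontology.obo"),
        "gaf": os.path.join(outdir, "annotations.gaf"),
        "targets": os.path.join(outdir, "targets.tsv"),
        "families": os.path.join(outdir, "families.tsv"),
        "coordinates": os.path.join(outdir, "coordinates.tsv"),
        "stress": os.path.join(outdir, "stress.tsv"),
    }
    _write_obo(data, paths["obo"])
    _write_gaf(data, paths["gaf"])
    for name, edges in sorted(data.edge_sources.items()):
        path = os.path.join(outdir, f"edges_{name}.tsv")
        paths[f"edges_{name}"] = path
        with open(path, "w") as out:
            for a, b in edges:
                out.write(f"{a}\t{b}\n")
    with open(paths["targets"], "w") as out:
        for mirna in sorted(data.target_sets):
            for gene in sorted(data.target_sets[mirna].targets):
                out.write(f"{mirna}\t{gene}\n")
    with open(paths["families"], "w") as out:
        for mirna in sorted(data.families):
            out.write(f"{mirna}\t{data.families[mirna]}\n")
    data.coordinates.sort_values(["chrom", "start", "mirna"]).to_csv(
        paths["coordinates"], sep="\t", header=False, index=False
    )
    with open(paths["stress"], "w") as out:
        for mirna in sorted(data.stress):
            for label in sorted(data.stress[mirna]):
                out.write(f"{mirna}\t{label}\n")
    return paths
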