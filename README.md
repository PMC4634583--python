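# mirnetsim

Functional similarity of plant microRNAs, scored through a GO-weighted
protein–protein interaction network.

## The problem

Plant miRNAs regulate small target-gene sets (often fewer than ten genes,
thanks to near-perfect miRNA–mRNA complementarity). Asking whether two
miRNAs do similar jobs by directly intersecting their target lists — the
Jaccard baseline — mostly returns zero, because small sets rarely overlap.
This package instead measures how *functionally close* the two target-gene
sets are inside the interactome:

1. **Weighted network (WPPIN).** Several PPI edge lists are merged into one
   non-redundant undirected network; each edge `(g, g′)` is weighted by the
   graph-based GO semantic similarity of its endpoint genes (one network
   per GO aspect: BP, CC, MF). Term similarity follows the ancestor-closure
   recursion with contribution factors 0.8 (`is_a`) and 0.6 (`part_of`);
   gene similarity aggregates the term matrix with a best-match average.
   Edges whose weight is missing (an unannotated endpoint) are kept in the
   topology but excluded from path search — missing is not zero.
2. **Gene-pair score.** For genes *i*, *j*,

   F(i, j) = max over minimum-hop paths P of ∏_{e ∈ P} weight(e),

   found by a weighted BFS with dominance pruning (per node and BFS depth
   only the best accumulated product survives — sound because all weights
   lie in (0, 1]). F(i, i) = 1; disconnected pairs score 0.
3. **miRNA-pair score.** With target sets of sizes *m*, *n* of which *m′*,
   *n′* fall outside the network,

   FS = ( Σ_rows max F + Σ_cols max F ) / ((m − m′) + (n − n′)),

   a modified best-match average over the in-network targets only.
4. **Evaluation.** Intrafamily / interfamily / random pair partitions (plus
   the genomic-cluster analogue under a 10-kb single-linkage chaining
   rule), Kruskal–Wallis and one-sided Wilcoxon rank-sum comparisons, and a
   1-positive-vs-99-negative prioritization ROC with mid-rank ties.

A synthetic-fixture generator produces toy ontologies (OBO), annotations
(GAF 2.2), edge lists, target tables, family labels, genome coordinates and
stress associations with controllable effect sizes, so the whole pipeline
runs and is tested without any external download.

## Worked example

Generate a small bundle, weight the network for the BP aspect, and score
two miRNA pairs (one intrafamily, one random):

```sh
mirnetsim fixtures --config fixture.cfg --seed 9 --outdir bundle
mirnetsim weight --obo bundle/ontology.obo --annotations bundle/annotations.gaf \
    --edges bundle/edges_dbA.tsv --edges bundle/edges_dbB.tsv \
    --aspect BP --out wppin.tsv
printf 'miR001\tmiR002\nmiR001\tmiR013\n' > pairs.tsv
mirnetsim pairsim --network wppin.tsv --targets bundle/targets.tsv \
    --pairs pairs.tsv --out pairsim.tsv
```

which logs `integrated network: 30 proteins, 48 interactions` /
`edges retained: 48, non-traversable: 0` and writes:

```text
mirna_i	mirna_j	score	m	n	m_excluded	n_excluded
miR001	miR002	0.898578	3	3	0	0
miR001	miR013	0.614510	3	3	0	0
```

`miR001` and `miR002` belong to the same planted family (75 % shared
targets wired into one network neighborhood), so their target sets sit
close in the weighted network and score 0.90; `miR001` vs the unrelated
`miR013` must route through longer, weaker paths and scores 0.61. The `m`,
`n` columns are the raw target-set sizes and `*_excluded` count targets
outside the network (none here). `mirnetsim matrix` then produces the
all-pairs score table and `mirnetsim evaluate` the partition rank tests —
on this bundle the intrafamily-vs-random one-sided rank-sum gives
p ≈ 3.4 × 10⁻⁴. Every command writes a `*.config.json` sidecar with its
resolved parameters.

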