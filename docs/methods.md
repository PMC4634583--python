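# Methods

## Model

The package scores the functional similarity of two miRNAs as the
functional closeness of their target-gene sets inside a weighted
protein–protein interaction network. The assumptions are: (i) interacting
proteins annotated to semantically similar GO terms are functionally
linked, so GO similarity is a sensible edge weight; (ii) functional
relatedness decays along interaction paths, which the product of edge
weights (all in (0, 1]) captures; (iii) the minimum-hop path is the
relevant route — weights only arbitrate among equally short paths; and
(iv) a best-match average is the right way to compare two small gene sets
whose elements pair off rather than align.

### Semantic similarity (graph-based)

For a term *A*, every ancestor *t* contributes
`s_A(t) = max over children c of t inside A's closure of w_rel · s_A(c)`,
with `s_A(A) = 1` and relation contribution factors `w_is_a = 0.8`,
`w_part_of = 0.6` (the published defaults of the graph-based measure;
exposed as a parameter). The semantic value `SV(A)` is the closure sum and

```
sim(A, B) = Σ_{t ∈ T_A ∩ T_B} (s_A(t) + s_B(t)) / (SV(A) + SV(B)).
```

Gene similarity aggregates the term matrix by best-match average
(`combine="bma"`, default, matching the common geneSim behavior) or by the
maximum entry (`combine="max"`). A gene with no annotation in an aspect
yields **missing**, never 0: conflating the two would silently zero out
every path product through such an edge. Evidence codes are not filtered
by default; an exclude-list (e.g. `IEA`) is available on the GAF reader.

### Path score

`F(i, j)` is the maximum product of edge weights over minimum-hop paths.
The search is a BFS whose frontier carries accumulated products; per node
and depth only the best product survives (dominance pruning). This is
exact because multiplying by a weight in (0, 1] is order-preserving —
also in floating point, where rounding is monotone, so the pruned search
is *bit-identical* to exhaustive enumeration (asserted in the tests).
Numerical choices: the search always runs from the lexicographically
smaller endpoint, making `F` exactly symmetric under rounding; among
equally scored optimal paths the lexicographically smallest node sequence
is the reported witness; disconnected pairs score 0 (the only value that
keeps the set-level denominator meaningful); `max_hops` is unlimited by
default, and capped pairs score 0 with a `capped` flag. The score rule
defaults to the plain product; `geometric_mean` (the n-th root, n = hop
count) is available for the reading of the method as an *average*
accumulated weight.

### Set aggregation

`FS = (Σ row maxima + Σ column maxima) / ((m − m′) + (n − n′))` over the
in-network ("effective") target sets; out-of-network genes contribute to
neither numerator nor denominator. Degenerate cases, which the formula
leaves open: both effective sets empty → status `undefined` (serialized
`NA`, never 0, since the denominator is 0); exactly one empty → score 0
with a warning (no best match exists for any gene). Gene-pair scores are
cached per network: a single-source layered sweep scores one gene against
all others at once, so all-pairs matrices cost one sweep per distinct
target gene rather than one search per pair.

### Evaluation protocol

Genomic clusters chain genes on one chromosome by single linkage on
sorted start coordinates, gap measured end-to-start, threshold 10 kb
(configurable); singletons are discarded. Pair partitions: intra and
inter pairs come from the chosen grouping (family or cluster); random
pairs are drawn, seeded, from pairs that are in *neither* grouping's
intra or inter class. Group comparisons use Kruskal–Wallis (≥3 groups)
and one-sided Mann–Whitney tests ("intra > other"); scipy's policy picks
exact enumeration for small tie-free samples and the tie-corrected normal
approximation otherwise. The prioritization experiment ranks each
positive pair against 99 seeded random negatives; ties get mid-ranks, so
all-equal scores yield AUC 0.5, the only defensible null. TPR/FPR are
computed at the 100 rank thresholds (negatives pooled across lists) and
the AUC by the trapezoidal rule; it agrees with the Mann–Whitney
`P(pos > neg) + ½P(tie)` estimate to within the 1/100 rank
discretization.

## Synthetic data

The generator emulates a desk-scale plant system: GO DAGs of 40 terms per
aspect as layered random DAGs with a single root (every term reaches the
root, as the closure recursion requires, depth ≤ 4, 20 % `part_of`
edges); 80 genes in an Erdős–Rényi network (p = 0.05) stitched to be
connected; 60 miRNAs — 10 families of 4 plus 20 singletons — with 5–10
targets each, matching the few-targets regime typical of plant miRNAs;
three 5-member stress groups labelled from a vocabulary of 12 abiotic and
3 biotic stresses; and genome coordinates that place four planted
clusters within the 10-kb chaining distance and everything else far
apart.

The designed effect: each family (or stress group) owns a shared target
pool covering the *effect* fraction of its members' targets; pool genes
form a planted clique and share a deep focal GO term per aspect, so the
signal exists both in topology and in edge weights. With effect 0 the
pools vanish and group membership carries no information — the
calibration null. Generation is a pure function of the spec; the same
seed reproduces every file byte-for-byte.

What passing on these fixtures does **not** show about real data: real
interactomes are scale-free and much larger, annotation depth is biased
toward well-studied genes, GO DAGs are far deeper with many multi-parent
terms, target-prediction noise is absent, and identifier heterogeneity
across source databases is reduced to a trivial normalization (uppercase,
strip isoform suffixes). The fixtures demonstrate correctness of the
computation and recoverability of a planted signal, not performance on
*A. thaliana*-scale inputs.

## Experiment sizes

The signal-recovery experiment uses 100 generated datasets (effect 0.75),
scoring 50 intrafamily vs 50 random pairs each; the null calibration uses
200 datasets with all effects at 0; the stress ROC uses 30 positive pairs
at 99 negatives each. These sizes give stable rank-test behavior (the
null Kolmogorov–Smirnov check needs ~200 p-values to be informative)
while each dataset stays small enough that a full pipeline run takes well
under a second.

## Known limitations

- Only `is_a` and `part_of` relations are used; `regulates`-type edges
  are skipped at parse time.
- The score is not a metric (no triangle inequality) and `FS` of
  identical miRNAs is 1 only when their effective sets coincide.
- No information-content similarity measures, no cross-aspect similarity,
  no target-site prediction: target tables are an input.
- The all-pairs matrix is computed densely; for interactome-scale inputs
  the per-gene single-source sweeps keep this tractable, but memory for
  the matrix itself grows quadratically in the miRNA count.
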