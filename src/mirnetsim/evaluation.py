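"""Evaluation protocol: pair partitions, rank tests and 1-vs-99 ROC.

miRNA pairs are partitioned into intra-group (same family or same genomic
cluster), inter-group and random pairs, where random pairs exclude every
intra/inter pair of *both* grouping kinds.  Group score distributions are
compared with Kruskal-Wallis and one-sided Wilcoxon rank-sum tests.  The
prioritization experiment ranks each positive pair against 99 randomly
drawn negative pairs and summarizes the 100-entry ranking lists as a ROC
curve with its AUC.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

Pair = Tuple[str, str]


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# genomic clusters


def assign_genomic_clusters(
    coords: pd.DataFrame,
    max_gap: int = 10_000,
) -> Dict[str, str]:
    """Chain miRNA genes into genomic clusters by single linkage.

    *coords* needs columns ``mirna, chrom, start, end`` (1-based inclusive
    positions).  Within a chromosome, genes sorted by start coordinate are
    chained while the gap between the previous gene's end and the next
    gene's start is at most *max_gap* (default 10 kb).  Singleton chains
    are discarded; the returned mapping covers clustered miRNAs only.
    """
    if coords["mirna"].duplicated().any():
        dupes = coords.loc[coords["mirna"].duplicated(), "mirna"].tolist()
        raise ValueError(f"duplicate miRNA ids in coordinates: {dupes}")
    assignment: Dict[str, str] = {}
    for chrom, block in coords.groupby("chrom", sort=True):
        block = block.sort_values(["start", "end", "mirna"])
        chains: List[List[str]] = []
        prev_end: Optional[int] = None
        for row in block.itertuples(index=False):
            if prev_end is not None and row.start - prev_end <= max_gap:
                chains[-1].append(row.mirna)
                prev_end = max(prev_end, row.end)
            else:
                chains.append([row.mirna])
                prev_end = row.end
        index = 0
        for chain in chains:
            if len(chain) < 2:
                continue
            index += 1
            for mirna in chain:
                assignment[mirna] = f"{chrom}_c{index}"
    return assignment


# ---------------------------------------------------------------------------
# pair partitions


@dataclass
class PairPartition:
    """Disjoint intra / inter / random unordered miRNA pair sets."""

    kind: str
    intra: FrozenSet[Pair]
    inter: FrozenSet[Pair]
    random: FrozenSet[Pair]
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        assert not (self.intra & self.inter)
        assert not (self.random & (self.intra | self.inter))


def _grouped_pairs(groups: Mapping[str, str]) -> Tuple[Set[Pair], Set[Pair]]:
    intra: Set[Pair] = set()
    inter: Set[Pair] = set()
    members = sorted(groups)
    for a, b in combinations(members, 2):
        if groups[a] == groups[b]:
            intra.add(_pair(a, b))
        else:
            inter.add(_pair(a, b))
    return intra, inter


def partition_pairs(
    mirnas: Sequence[str],
    families: Mapping[str, str],
    clusters: Mapping[str, str],
    kind: str,
    n_random: int,
    seed: int,
) -> PairPartition:
    """Split miRNA pairs into intra-group, inter-group and random classes.

    The intra/inter classes come from the grouping named by *kind*
    (``"family"`` or ``"cluster"``); the random class is drawn from all
    remaining pairs after excluding the intra and inter pairs of *both*
    groupings.  Deterministic under a fixed *seed*.
    """
    if kind not in ("family", "cluster"):
        raise ValueError(f"unknown grouping kind {kind!r}")
    groups = families if kind == "family" else clusters
    label_counts: Dict[str, int] = {}
    for label in groups.values():
        label_counts[label] = label_counts.get(label, 0) + 1
    if not any(count >= 2 for count in label_counts.values()):
        raise ValueError(f"no {kind} group has two or more members")
    intra, inter = _grouped_pairs(groups)
    fam_intra, fam_inter = _grouped_pairs(families)
    clu_intra, clu_inter = _grouped_pairs(clusters)
    excluded = fam_intra | fam_inter | clu_intra | clu_inter
    eligible = sorted(
        p for p in (_pair(a, b) for a, b in combinations(sorted(set(mirnas)), 2))
        if p not in excluded
    )
    if n_random > len(eligible):
        raise ValueError(
            f"requested {n_random} random pairs but only {len(eligible)} eligible"
        )
    rng = random.Random(seed)
    sample = frozenset(rng.sample(eligible, n_random))
    return PairPartition(kind, frozenset(intra), frozenset(inter), sample, seed)


# ---------------------------------------------------------------------------
# rank-based group comparison


@dataclass
class GroupComparison:
    """Kruskal-Wallis over all groups plus one-sided pairwise rank-sums."""

    kruskal_h: Optional[float]
    kruskal_p: Optional[float]
    pairwise: Dict[Tuple[str, str], Tuple[float, float]]


def group_comparison(
    scores: Mapping[str, Sequence[float]],
    reference: Optional[str] = None,
) -> GroupComparison:
    """Compare score distributions across labelled groups.

    Runs the Kruskal-Wallis H test when three or more groups are given,
    plus a one-sided Wilcoxon rank-sum (Mann-Whitney) test of
    ``reference > other`` for every other group (*reference* defaults to
    the first key).  Exact p-values are used for small tie-free samples,
    the tie-corrected normal approximation otherwise (scipy's policy).
    """
    labels = list(scores)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for label in labels:
        if len(scores[label]) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")
    if reference is None:
        reference = labels[0]
    if reference not in scores:
        raise ValueError(f"reference group {reference!r} not present")
    kruskal_h = kruskal_p = None
    if len(labels) >= 3:
        kruskal_h, kruskal_p = stats.kruskal(*(scores[label] for label in labels))
        kruskal_h, kruskal_p = float(kruskal_h), float(kruskal_p)
    pairwise: Dict[Tuple[str, str], Tuple[float, float]] = {}
    for other in labels:
        if other == reference:
            continue
        u, p = stats.mannwhitneyu(
            scores[reference], scores[other], alternative="greater"
        )
        pairwise[(reference, other)] = (float(u), float(p))
    return GroupComparison(kruskal_h, kruskal_p, pairwise)


# ---------------------------------------------------------------------------
# 1-vs-99 prioritization ROC


@dataclass
class RankingList:
    """One positive pair with its sampled negatives and mid-rank."""

    positive: Pair
    positive_score: float
    negative_scores: Tuple[float, ...]
    rank: float  # mid-rank of the positive within the 100-entry list


@dataclass
class RankingExperiment:
    """Aggregate of all ranking lists: TPR/FPR per rank threshold and AUC."""

    lists: List[RankingList]
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    seed: Optional[int] = None


def _mid_rank(value: float, others: Sequence[float]) -> float:
    greater = sum(1 for s in others if s > value)
    ties = sum(1 for s in others if s == value)
    return greater + (ties + 2) / 2.0  # +1 for itself, mid-rank among ties


def roc_prioritization(
    positives: Sequence[Pair],
    negative_pool: Sequence[Pair],
    scores: Mapping[Pair, float],
    negatives_per_positive: int = 99,
    seed: int = 0,
) -> RankingExperiment:
    """Rank each positive pair against randomly drawn negative pairs.

    For every positive a list of ``1 + negatives_per_positive`` scored
    pairs is formed; the positive's mid-rank within its list is recorded
    (ties share the average rank, so uninformative scores give AUC 0.5).
    TPR at threshold t is the fraction of positives ranked <= t, FPR the
    analogous fraction over all pooled negatives; the AUC is the
    trapezoidal area under the resulting curve.
    """
    pool = sorted(set(_pair(*p) for p in negative_pool))
    if len(pool) < negatives_per_positive:
        raise ValueError(
            f"negative pool ({len(pool)}) smaller than "
            f"negatives_per_positive ({negatives_per_positive})"
        )
    rng = random.Random(seed)
    lists: List[RankingList] = []
    negative_ranks: List[float] = []
    for positive in positives:
        positive = _pair(*positive)
        sampled = rng.sample(pool, negatives_per_positive)
        pos_score = scores[positive]
        neg_scores = tuple(scores[p] for p in sampled)
        lists.append(
            RankingList(positive, pos_score, neg_scores, _mid_rank(pos_score, neg_scores))
        )
        for i, s in enumerate(neg_scores):
            others = list(neg_scores[:i]) + list(neg_scores[i + 1:]) + [pos_score]
            negative_ranks.append(_mid_rank(s, others))
    list_size = negatives_per_positive + 1
    thresholds = np.arange(1, list_size + 1)
    pos_ranks = np.array([entry.rank for entry in lists])
    neg_ranks = np.array(negative_ranks)
    tpr = np.array([(pos_ranks <= t).mean() for t in thresholds])
    fpr = np.array([(neg_ranks <= t).mean() for t in thresholds])
    auc = float(np.trapezoid(np.r_[0.0, tpr], np.r_[0.0, fpr]))
    return RankingExperiment(lists, thresholds, tpr, fpr, auc, seed)


# ---------------------------------------------------------------------------
# stress-response experiment


def stress_pair_experiment(
    associations: Mapping[str, Iterable[str]],
    all_mirnas: Sequence[str],
    n_negative_sets: int = 50,
    seed: int = 0,
) -> Tuple[FrozenSet[Pair], List[FrozenSet[Pair]]]:
    """Positive pairs sharing a stress label plus matched negative sets.

    Positives are all unordered pairs of miRNAs sharing at least one
    stress label.  Each of the *n_negative_sets* negative sets has the
    same cardinality as the positive set and is drawn without replacement
    from pairs sharing no label.  Deterministic under *seed*.
    """
    labels = {m: frozenset(v) for m, v in associations.items()}
    mirnas = sorted(set(all_mirnas))
    positives: Set[Pair] = set()
    non_sharing: List[Pair] = []
    for a, b in combinations(mirnas, 2):
        if labels.get(a, frozenset()) & labels.get(b, frozenset()):
            positives.add(_pair(a, b))
        else:
            non_sharing.append(_pair(a, b))
    if not positives:
        raise ValueError("no two miRNAs share a stress label")
    if len(non_sharing) < len(positives):
        raise ValueError(
            f"only {len(non_sharing)} non-sharing pairs available for "
            f"negative sets of size {len(positives)}"
        )
    rng = random.Random(seed)
    negative_sets = [
        frozenset(rng.sample(non_sharing, len(positives)))
        for _ in range(n_negative_sets)
    ]
    return frozenset(positives), negative_sets


def load_family_table(path: str) -> Dict[str, str]:
    """Read a 2-column (mirna, family) TSV."""
    mapping: Dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"family table line has <2 columns: {line!r}")
            mapping[cols[0]] = cols[1]
    return mapping


def load_coordinate_table(path: str) -> pd.DataFrame:
    """Read a BED-like TSV with columns mirna, chrom, start, end[, strand]."""
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["mirna", "chrom", "start", "end", "strand"],
        usecols=[0, 1, 2, 3, 4],
    )
    return frame


def load_stress_table(path: str) -> Dict[str, FrozenSet[str]]:
    """Read a 2-column (mirna, stress label) TSV into label sets."""
    raw: Dict[str, set] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"stress table line has <2 columns: {line!r}")
            raw.setdefault(cols[0], set()).add(cols[1])
    return {m: frozenset(v) for m, v in raw.items()}
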