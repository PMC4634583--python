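"""End-to-end experiment drivers gluing the pipeline stages together.

These run the complete workflow on a synthetic bundle: weight the PPI
network for one GO aspect, score miRNA pairs through the path-based
target-set similarity, and feed the scores into the rank-test and
1-vs-99 ROC evaluations.
"""

from __future__ import annotations

import random
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .evaluation import (
    Pair,
    RankingExperiment,
    assign_genomic_clusters,
    partition_pairs,
    roc_prioritization,
    stress_pair_experiment,
    _pair,
)
from .network import WeightedNetwork, weight_network
from .pathsim import PathSearchConfig
from .setsim import TargetGeneSet, target_set_similarity
from .synth import FixtureSpec, SyntheticData, generate_dataset


def build_weighted_network(
    data: SyntheticData, aspect: str = "BP", **weight_kwargs
) -> WeightedNetwork:
    return weight_network(
        data.network, data.annotations, data.ontologies[aspect], **weight_kwargs
    )


class PairScorer(Mapping):
    """Lazy pair -> similarity mapping backed by the scoring pipeline.

    Scores are computed on first access and memoized, so ROC experiments
    only ever score the pairs they actually sample.  Undefined pairs
    (both target sets outside the network) surface as NaN.
    """

    def __init__(
        self,
        target_sets: Mapping[str, TargetGeneSet],
        net: WeightedNetwork,
        cfg: PathSearchConfig = PathSearchConfig(),
    ) -> None:
        self._sets = target_sets
        self._net = net
        self._cfg = cfg
        self._cache: Dict[Pair, float] = {}

    def __getitem__(self, pair: Pair) -> float:
        pair = _pair(*pair)
        if pair not in self._cache:
            result = target_set_similarity(
                self._sets[pair[0]], self._sets[pair[1]], self._net, self._cfg
            )
            self._cache[pair] = np.nan if result.score is None else result.score
        return self._cache[pair]

    def __iter__(self):
        return iter(self._cache)

    def __len__(self) -> int:
        return len(self._cache)

    def score_many(self, pairs: Iterable[Pair]) -> list:
        return [self[p] for p in pairs]


def family_rank_experiment(
    spec: FixtureSpec,
    n_intra: int = 50,
    n_random: int = 50,
    aspect: str = "BP",
    cfg: PathSearchConfig = PathSearchConfig(),
) -> Tuple[float, float]:
    """One-sided rank-sum test of intrafamily vs random miRNA-pair scores.

    Generates the dataset for ``spec`` (its seed drives everything),
    weights the network, samples ``n_intra`` intrafamily and ``n_random``
    random pairs, scores them and returns ``(U, p)`` for the alternative
    "intrafamily scores are larger".
    """
    data = generate_dataset(spec)
    net = build_weighted_network(data, aspect)
    clusters = assign_genomic_clusters(data.coordinates)
    partition = partition_pairs(
        sorted(data.target_sets),
        data.families,
        clusters,
        kind="family",
        n_random=n_random,
        seed=spec.seed,
    )
    rng = random.Random(spec.seed)
    intra = sorted(partition.intra)
    if n_intra < len(intra):
        intra = rng.sample(intra, n_intra)
    scorer = PairScorer(data.target_sets, net, cfg)
    intra_scores = [s for s in scorer.score_many(intra) if not np.isnan(s)]
    random_scores = [
        s for s in scorer.score_many(sorted(partition.random)) if not np.isnan(s)
    ]
    u, p = stats.mannwhitneyu(intra_scores, random_scores, alternative="greater")
    return float(u), float(p)


def stress_roc_experiment(
    spec: FixtureSpec,
    negatives_per_positive: int = 99,
    aspect: str = "BP",
    cfg: PathSearchConfig = PathSearchConfig(),
) -> RankingExperiment:
    """1-vs-99 prioritization of stress-sharing miRNA pairs.

    Positives are pairs sharing a stress label; the negative pool
    excludes same-family, same-cluster and same-stress pairs, mirroring
    the evaluation protocol.
    """
    data = generate_dataset(spec)
    net = build_weighted_network(data, aspect)
    clusters = assign_genomic_clusters(data.coordinates)
    mirnas = sorted(data.target_sets)
    positives, _ = stress_pair_experiment(data.stress, mirnas, 1, seed=spec.seed)
    from itertools import combinations

    def same_group(a: str, b: str, groups: Mapping[str, str]) -> bool:
        return a in groups and b in groups and groups[a] == groups[b]

    pool = [
        _pair(a, b)
        for a, b in combinations(mirnas, 2)
        if _pair(a, b) not in positives
        and not same_group(a, b, data.families)
        and not same_group(a, b, clusters)
    ]
    scorer = PairScorer(data.target_sets, net, cfg)
    return roc_prioritization(
        sorted(positives),
        pool,
        scorer,
        negatives_per_positive=negatives_per_positive,
        seed=spec.seed,
    )
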