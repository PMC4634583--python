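"""Evaluation protocol: clustering rule, partitions, rank tests, ROC."""

import math
import random
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirnetsim import (
    assign_genomic_clusters,
    group_comparison,
    partition_pairs,
    roc_prioritization,
    stress_pair_experiment,
)


def _coords(rows):
    return pd.DataFrame(rows, columns=["mirna", "chrom", "start", "end", "strand"])


class TestGenomicClusters:
    def test_under_threshold_pair_clusters(self):
        coords = _coords(
            [("m1", "Chr1", 1000, 1100, "+"), ("m2", "Chr1", 6100, 6200, "+")]
        )
        clusters = assign_genomic_clusters(coords)
        assert clusters["m1"] == clusters["m2"]

    def test_different_chromosomes_never_cluster(self):
        coords = _coords(
            [("m1", "Chr1", 1000, 1100, "+"), ("m2", "Chr2", 1000, 1100, "+")]
        )
        assert assign_genomic_clusters(coords) == {}

    def test_single_linkage_chain_spans_beyond_gap(self):
        # gaps of 9 kb and 9 kb: ends 18 kb apart, still one 3-member chain
        coords = _coords(
            [
                ("m1", "Chr1", 1000, 1100, "+"),
                ("m2", "Chr1", 10100, 10200, "+"),
                ("m3", "Chr1", 19200, 19300, "+"),
            ]
        )
        clusters = assign_genomic_clusters(coords)
        assert clusters["m1"] == clusters["m2"] == clusters["m3"]

    def test_gap_above_threshold_breaks_chain(self):
        coords = _coords(
            [("m1", "Chr1", 1000, 1100, "+"), ("m2", "Chr1", 20000, 20100, "+")]
        )
        assert assign_genomic_clusters(coords) == {}

    def test_singletons_discarded(self):
        coords = _coords(
            [
                ("m1", "Chr1", 1000, 1100, "+"),
                ("m2", "Chr1", 5000, 5100, "+"),
                ("m3", "Chr1", 90000, 90100, "+"),
            ]
        )
        clusters = assign_genomic_clusters(coords)
        assert set(clusters) == {"m1", "m2"}

    def test_duplicate_ids_raise(self):
        coords = _coords(
            [("m1", "Chr1", 1000, 1100, "+"), ("m1", "Chr1", 2000, 2100, "+")]
        )
        with pytest.raises(ValueError, match="duplicate"):
            assign_genomic_clusters(coords)

    def test_custom_gap(self):
        coords = _coords(
            [("m1", "Chr1", 1000, 1100, "+"), ("m2", "Chr1", 6100, 6200, "+")]
        )
        assert assign_genomic_clusters(coords, max_gap=1000) == {}


class TestPartitions:
    def test_two_families_of_two(self):
        families = {"a1": "F1", "a2": "F1", "b1": "F2", "b2": "F2"}
        part = partition_pairs(
            list(families) + ["x", "y"], families, {}, "family", n_random=1, seed=0
        )
        assert part.intra == {("a1", "a2"), ("b1", "b2")}
        assert len(part.inter) == 4

    def test_seed_determinism(self):
        families = {"a1": "F1", "a2": "F1"}
        mirnas = [f"m{i}" for i in range(10)] + ["a1", "a2"]
        p1 = partition_pairs(mirnas, families, {}, "family", 5, seed=3)
        p2 = partition_pairs(mirnas, families, {}, "family", 5, seed=3)
        assert p1.random == p2.random

    def test_random_disjoint_from_grouped_pairs_exhaustive(self):
        mirnas = [f"m{i}" for i in range(10)]
        families = {"m0": "F1", "m1": "F1", "m2": "F2", "m3": "F2"}
        clusters = {"m4": "C1", "m5": "C1"}
        part = partition_pairs(mirnas, families, clusters, "family", 8, seed=1)
        grouped = set()
        labelled_f = sorted(families)
        labelled_c = sorted(clusters)
        for a, b in combinations(labelled_f, 2):
            grouped.add(tuple(sorted((a, b))))
        for a, b in combinations(labelled_c, 2):
            grouped.add(tuple(sorted((a, b))))
        assert not part.random & grouped
        assert not part.random & part.intra
        assert not part.random & part.inter

    def test_no_multimember_group_raises(self):
        with pytest.raises(ValueError, match="two or more"):
            partition_pairs(["a", "b"], {"a": "F1"}, {}, "family", 1, seed=0)

    def test_oversized_random_request_raises(self):
        families = {"a": "F1", "b": "F1"}
        with pytest.raises(ValueError, match="eligible"):
            partition_pairs(["a", "b", "c"], families, {}, "family", 100, seed=0)


class TestGroupComparison:
    def test_identical_groups_have_zero_h(self):
        scores = {"intra": [1, 2, 3], "inter": [1, 2, 3], "random": [1, 2, 3]}
        result = group_comparison(scores)
        assert result.kruskal_h == pytest.approx(0.0)

    def test_exact_one_sided_rank_sum_extreme_arrangement(self):
        # most extreme split of 6 ranks: p = 1 / C(6,3) = 0.05
        result = group_comparison({"intra": [10, 11, 12], "other": [1, 2, 3]})
        assert result.pairwise[("intra", "other")][1] == pytest.approx(1 / 20)

    def test_h_matches_textbook_formula(self):
        rng = random.Random(8)
        groups = {
            label: [rng.random() for _ in range(n)]
            for label, n in (("a", 6), ("b", 8), ("c", 5))
        }
        result = group_comparison(groups)
        pooled = sorted(
            (value, label) for label, values in groups.items() for value in values
        )
        ranks = {}
        for rank, (value, label) in enumerate(pooled, start=1):
            ranks.setdefault(label, []).append(rank)
        n_total = len(pooled)
        h = 12 / (n_total * (n_total + 1)) * sum(
            len(r) * (np.mean(r) - (n_total + 1) / 2) ** 2 for r in ranks.values()
        )
        assert result.kruskal_h == pytest.approx(h)

    def test_two_groups_skip_kruskal(self):
        result = group_comparison({"intra": [1, 2], "other": [3, 4]})
        assert result.kruskal_h is None
        assert ("intra", "other") in result.pairwise

    def test_small_group_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            group_comparison({"intra": [1], "other": [1, 2]})


def _pairs(prefix, n):
    return [(f"{prefix}{i}a", f"{prefix}{i}b") for i in range(n)]


class TestRocPrioritization:
    def test_perfect_separation_gives_auc_one(self):
        positives = _pairs("p", 10)
        negatives = _pairs("n", 150)
        scores = {tuple(sorted(p)): 1.0 for p in positives}
        scores.update({tuple(sorted(p)): 0.1 for p in negatives})
        exp = roc_prioritization(positives, negatives, scores, seed=0)
        assert exp.auc == pytest.approx(1.0)
        assert all(entry.rank == 1.0 for entry in exp.lists)

    def test_all_tied_scores_give_auc_half(self):
        positives = _pairs("p", 10)
        negatives = _pairs("n", 150)
        scores = {tuple(sorted(p)): 0.5 for p in positives + negatives}
        exp = roc_prioritization(positives, negatives, scores, seed=0)
        assert exp.auc == pytest.approx(0.5)
        assert all(entry.rank == 50.5 for entry in exp.lists)

    def test_auc_matches_mann_whitney_identity(self):
        # positives drawn from the higher of two overlapping distributions
        rng = random.Random(5)
        positives = _pairs("p", 40)
        negatives = _pairs("n", 200)
        scores = {}
        for p in positives:
            scores[tuple(sorted(p))] = rng.gauss(0.6, 0.15)
        for p in negatives:
            scores[tuple(sorted(p))] = rng.gauss(0.4, 0.15)
        exp = roc_prioritization(positives, negatives, scores, seed=9)
        wins = ties = total = 0
        for entry in exp.lists:
            for neg in entry.negative_scores:
                total += 1
                if entry.positive_score > neg:
                    wins += 1
                elif entry.positive_score == neg:
                    ties += 1
        estimate = (wins + 0.5 * ties) / total
        assert exp.auc == pytest.approx(estimate, abs=1 / 100)

    def test_each_list_has_hundred_entries_and_valid_rank(self):
        positives = _pairs("p", 5)
        negatives = _pairs("n", 120)
        rng = random.Random(1)
        scores = {
            tuple(sorted(p)): rng.random() for p in positives + negatives
        }
        exp = roc_prioritization(positives, negatives, scores, seed=2)
        for entry in exp.lists:
            assert len(entry.negative_scores) == 99
            assert 1.0 <= entry.rank <= 100.0

    def test_small_pool_raises(self):
        with pytest.raises(ValueError, match="pool"):
            roc_prioritization(_pairs("p", 1), _pairs("n", 10), {}, seed=0)


class TestStressExperiment:
    def test_three_mirnas_one_label_give_three_pairs(self):
        assoc = {"m1": {"drought"}, "m2": {"drought"}, "m3": {"drought"}}
        mirnas = ["m1", "m2", "m3", "m4", "m5", "m6"]
        positives, negatives = stress_pair_experiment(assoc, mirnas, 2, seed=0)
        assert len(positives) == 3

    def test_negative_sets_share_no_label_exhaustive(self):
        assoc = {
            "m1": {"drought"},
            "m2": {"drought", "cold"},
            "m3": {"cold"},
            "m4": {"heat"},
        }
        mirnas = [f"m{i}" for i in range(1, 9)]
        positives, negatives = stress_pair_experiment(assoc, mirnas, 5, seed=3)
        for negative_set in negatives:
            assert len(negative_set) == len(positives)
            for a, b in negative_set:
                shared = assoc.get(a, set()) & assoc.get(b, set())
                assert not shared

    def test_seed_reproducibility(self):
        assoc = {"m1": {"x"}, "m2": {"x"}}
        mirnas = [f"m{i}" for i in range(1, 8)]
        run1 = stress_pair_experiment(assoc, mirnas, 3, seed=7)
        run2 = stress_pair_experiment(assoc, mirnas, 3, seed=7)
        assert run1 == run2

    def test_no_sharing_pair_raises(self):
        with pytest.raises(ValueError, match="share"):
            stress_pair_experiment({"m1": {"x"}}, ["m1", "m2"], 1, seed=0)
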