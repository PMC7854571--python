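"""Clustering, optimal cluster-to-class matching, and P/R/F1 scoring."""

import itertools

import numpy as np
import pytest

from cryocdae.clustering import (
    ClusterAssignment,
    cluster_stack,
    contingency_table,
    evaluate_clustering,
    match_clusters,
    score,
)
from cryocdae.stack import ImageStack


def _groups_stack():
    """4 well-separated constant-valued image groups, 5 images each."""
    levels = [0.0, 0.3, 0.6, 0.9]
    pixels = np.concatenate(
        [np.full((5, 8, 8), v, dtype=np.float32) for v in levels]
    )
    labels = np.repeat(np.arange(4), 5)
    return ImageStack(pixels, labels=labels)


class TestClusterStack:
    @pytest.mark.parametrize("method", ["kmeans", "hierarchical"])
    def test_separable_groups_recovered_exactly(self, method):
        stack = _groups_stack()
        report = evaluate_clustering(stack, stack.labels, K=4, method=method, seed=0)
        assert report.macro_f1 == 1.0 and report.accuracy == 1.0

    def test_same_seed_same_assignment(self, rng):
        stack = ImageStack(rng.random((30, 6, 6), dtype=np.float32))
        a = cluster_stack(stack, K=3, seed=5)
        b = cluster_stack(stack, K=3, seed=5)
        assert np.array_equal(a.labels, b.labels)

    def test_hierarchical_k_equals_n_is_singletons(self, rng):
        stack = ImageStack(rng.random((6, 4, 4), dtype=np.float32))
        assign = cluster_stack(stack, K=6, method="hierarchical")
        assert len(set(assign.labels.tolist())) == 6

    def test_k_larger_than_stack_rejected(self, rng):
        stack = ImageStack(rng.random((3, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError):
            cluster_stack(stack, K=4)


class TestMatchClusters:
    def test_recovers_permutation_of_perfect_clustering(self):
        truth = np.repeat(np.arange(4), 10)
        permuted = (truth + 2) % 4  # relabeled clusters
        assign = ClusterAssignment(labels=permuted, K=4, method="kmeans")
        mapping = match_clusters(assign, truth)
        assert all(mapping[(c + 2) % 4] == c for c in range(4))

    def test_small_contingency_example(self):
        # table [[5,0],[1,4]]: identity mapping, 9/10 correct
        truth = np.array([0] * 5 + [0] + [1] * 4)
        clusters = np.array([0] * 5 + [1] * 5)
        assign = ClusterAssignment(labels=clusters, K=2, method="kmeans")
        table = contingency_table(assign, truth)
        assert table.tolist() == [[5, 0], [1, 4]]
        mapping = match_clusters(assign, truth)
        assert mapping == {0: 0, 1: 1}
        assert score(assign, truth, mapping).accuracy == pytest.approx(0.9)

    def test_matches_brute_force_over_all_permutations(self, rng):
        for trial in range(5):
            table = rng.integers(0, 10, size=(4, 4))
            truth = np.repeat(np.arange(4), table.sum(axis=0))
            labels = np.concatenate(
                [np.repeat(np.arange(4), table[:, c]) for c in range(4)]
            )
            assign = ClusterAssignment(labels=labels, K=4, method="kmeans")
            mapping = match_clusters(assign, truth)
            achieved = sum(table[g, c] for g, c in mapping.items())
            best = max(
                sum(table[g, c] for g, c in enumerate(perm))
                for perm in itertools.permutations(range(4))
            )
            assert achieved == best

    def test_cluster_count_mismatch_padded(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        assign = ClusterAssignment(labels=np.array([0, 0, 1, 1, 1, 1]), K=2, method="kmeans")
        mapping = match_clusters(assign, truth)
        assert set(mapping) == {0, 1}  # only real clusters mapped


class TestScore:
    def test_perfect_clustering_scores_one(self):
        truth = np.repeat(np.arange(3), 4)
        assign = ClusterAssignment(labels=truth.copy(), K=3, method="kmeans")
        report = score(assign, truth, match_clusters(assign, truth))
        assert report.macro_f1 == report.macro_precision == report.macro_recall == 1.0

    def test_hand_computed_contingency_arithmetic(self):
        # cluster 0 holds 5 class-0 images plus 1 stray class-1 image;
        # cluster 1 holds the remaining 4 class-1 images
        truth = np.array([0] * 5 + [1] + [1] * 4)
        assign = ClusterAssignment(labels=np.array([0] * 6 + [1] * 4), K=2, method="kmeans")
        report = score(assign, truth, {0: 0, 1: 1})
        row0 = report.per_class.iloc[0]
        row1 = report.per_class.iloc[1]
        assert row0["precision"] == pytest.approx(5 / 6)
        assert row0["recall"] == pytest.approx(1.0)
        assert row1["precision"] == pytest.approx(1.0)
        assert row1["recall"] == pytest.approx(4 / 5)
        f1_0 = 2 * (5 / 6) / (5 / 6 + 1)
        f1_1 = 2 * (4 / 5) / (1 + 4 / 5)
        assert report.macro_f1 == pytest.approx((f1_0 + f1_1) / 2)
        assert report.macro_f1 == pytest.approx(0.898, abs=1e-3)

    def test_single_swallowing_cluster_macro_recall(self):
        truth = np.repeat(np.arange(4), 5)
        assign = ClusterAssignment(labels=np.zeros(20, dtype=int), K=4, method="kmeans")
        report = score(assign, truth, match_clusters(assign, truth))
        assert report.macro_recall == pytest.approx(0.25)

    def test_metrics_invariant_to_cluster_relabeling(self, rng):
        truth = rng.integers(0, 3, size=40)
        labels = rng.integers(0, 3, size=40)
        assign = ClusterAssignment(labels=labels, K=3, method="kmeans")
        base = score(assign, truth, match_clusters(assign, truth))
        perm = np.array([2, 0, 1])
        shuffled = ClusterAssignment(labels=perm[labels], K=3, method="kmeans")
        other = score(shuffled, truth, match_clusters(shuffled, truth))
        assert other.macro_f1 == pytest.approx(base.macro_f1)
        assert other.accuracy == pytest.approx(base.accuracy)

    def test_macro_f1_bounded_by_class_f1(self, rng):
        truth = rng.integers(0, 4, size=60)
        labels = rng.integers(0, 4, size=60)
        assign = ClusterAssignment(labels=labels, K=4, method="kmeans")
        report = score(assign, truth, match_clusters(assign, truth))
        f1s = report.per_class["f1"]
        assert f1s.min() - 1e-12 <= report.macro_f1 <= f1s.max() + 1e-12

    def test_report_frame_has_macro_row(self):
        truth = np.repeat(np.arange(2), 5)
        assign = ClusterAssignment(labels=truth.copy(), K=2, method="kmeans")
        frame = score(assign, truth, match_clusters(assign, truth)).to_frame()
        assert list(frame["class"])[-1] == "macro"
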