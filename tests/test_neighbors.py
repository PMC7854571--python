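"""Neighborhood graphs and mean-image pseudo-targets."""

import numpy as np
import pytest

from cryocdae.metrics import psnr
from cryocdae.neighbors import (
    NeighborConfig,
    NeighborGraph,
    mean_targets,
    nearest_neighbors,
    neighbor_mean_stack,
    pairwise_distances,
)
from cryocdae.simulate import add_noise
from cryocdae.stack import ImageStack, SNRLevel


def _stack(arr) -> ImageStack:
    return ImageStack(np.asarray(arr, dtype=np.float32))


class TestPairwiseDistances:
    def test_identical_images_have_zero_distance(self):
        img = np.random.default_rng(0).random((4, 4))
        d = pairwise_distances(_stack([img, img]))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_single_pixel_difference_closed_form(self):
        a = np.zeros((4, 4))
        b = a.copy()
        b[1, 2] = 0.25
        d = pairwise_distances(_stack([a, b]))
        assert d[0, 1] == pytest.approx(0.25)

    def test_matches_brute_force_double_loop(self, rng):
        pixels = rng.random((10, 6, 6), dtype=np.float32)
        d = pairwise_distances(ImageStack(pixels))
        flat = pixels.reshape(10, -1).astype(np.float64)
        for i in range(10):
            for j in range(10):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((flat[i] - flat[j]) ** 2).sum()), abs=1e-9
                )

    def test_correlation_metric_and_constant_image_error(self, rng):
        pixels = rng.random((5, 4, 4), dtype=np.float32)
        d = pairwise_distances(ImageStack(pixels), metric="correlation")
        assert np.allclose(np.diag(d), 0.0, atol=1e-12)
        r = np.corrcoef(pixels.reshape(5, -1))
        assert np.allclose(d, 1 - r, atol=1e-6)
        pixels[0] = 0.7
        with pytest.raises(ValueError, match="constant"):
            pairwise_distances(ImageStack(pixels), metric="correlation")


class TestNearestNeighbors:
    def test_k1_with_self_is_identity(self, rng):
        d = pairwise_distances(ImageStack(rng.random((6, 4, 4), dtype=np.float32)))
        graph = nearest_neighbors(d, NeighborConfig(k=1))
        assert np.array_equal(graph.indices[:, 0], np.arange(6))

    def test_collinear_points_excluding_self(self):
        # distances 0/1/2 on a line: each point's 2 nearest others are correct
        imgs = np.zeros((3, 4, 4))
        imgs[1] += 1.0 / 4.0
        imgs[2] += 2.0 / 4.0
        d = pairwise_distances(_stack(imgs))
        graph = nearest_neighbors(d, NeighborConfig(k=2, include_self=False))
        assert list(graph.indices[0]) == [1, 2]
        assert list(graph.indices[2]) == [1, 0]

    def test_agrees_with_full_sort_brute_force(self, rng):
        d = pairwise_distances(ImageStack(rng.random((20, 5, 5), dtype=np.float32)))
        graph = nearest_neighbors(d, NeighborConfig(k=5))
        for i in range(20):
            assert list(graph.indices[i]) == list(np.argsort(d[i], kind="stable")[:5])
            assert np.all(np.diff(graph.distances[i]) >= 0)

    def test_ties_break_to_lower_index(self):
        d = np.zeros((4, 4))  # all-equal distances
        graph = nearest_neighbors(d, NeighborConfig(k=2))
        assert list(graph.indices[3]) == [0, 1]

    def test_k_out_of_range_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            nearest_neighbors(d, NeighborConfig(k=4))
        with pytest.raises(ValueError):
            nearest_neighbors(d, NeighborConfig(k=3, include_self=False))


class TestMeanTargets:
    def test_identical_neighbors_reproduce_the_image(self):
        img = np.random.default_rng(3).random((4, 4)).astype(np.float32)
        stack = _stack([img] * 5)
        out = neighbor_mean_stack(stack, NeighborConfig(k=3))
        assert np.allclose(out.pixels, stack.pixels, atol=1e-6)

    def test_k1_include_self_is_identity_map(self, rng):
        stack = ImageStack(rng.random((7, 4, 4), dtype=np.float32))
        out = neighbor_mean_stack(stack, NeighborConfig(k=1))
        assert np.array_equal(out.pixels, stack.pixels)

    def test_labels_passed_through(self, rng):
        stack = ImageStack(rng.random((6, 4, 4), dtype=np.float32), labels=np.arange(6) % 3)
        out = neighbor_mean_stack(stack, NeighborConfig(k=2))
        assert np.array_equal(out.labels, stack.labels)

    def test_mean_within_convex_hull_of_contributors(self, rng):
        stack = ImageStack(rng.random((12, 8, 8), dtype=np.float32))
        graph = nearest_neighbors(pairwise_distances(stack), NeighborConfig(k=4))
        out = mean_targets(stack, graph)
        for i in range(12):
            contrib = stack.pixels[graph.indices[i]]
            assert np.all(out.pixels[i] >= contrib.min(axis=0) - 1e-6)
            assert np.all(out.pixels[i] <= contrib.max(axis=0) + 1e-6)

    def test_noise_variance_reduced_by_k(self):
        """Mean over k i.i.d. noisy copies has ~sigma^2/k residual variance."""
        rng = np.random.default_rng(5)
        clean = rng.random((16, 16)).astype(np.float32)
        k, trials, sigma = 16, 100, 0.3
        ratios = []
        for t in range(trials):
            noise = rng.normal(0, sigma, size=(k, 16, 16)).astype(np.float32)
            stack = ImageStack(clean[None] + noise)
            graph = nearest_neighbors(pairwise_distances(stack), NeighborConfig(k=k))
            target = mean_targets(stack, graph)
            ratios.append(np.var(target.pixels[0] - clean) / sigma**2)
        assert np.mean(ratios) == pytest.approx(1.0 / k, rel=0.20)

    def test_wrong_graph_rejected(self, rng):
        stack = ImageStack(rng.random((5, 4, 4), dtype=np.float32))
        graph = NeighborGraph(indices=np.zeros((9, 2)), distances=np.zeros((9, 2)))
        with pytest.raises(ValueError):
            mean_targets(stack, graph)


class TestStackLevelProperties:
    def test_neighbor_purity_exceeds_chance_on_clean_classes(self, tiny_datasets):
        tiers, _ = tiny_datasets
        clean = tiers[-1]
        graph = nearest_neighbors(pairwise_distances(clean), NeighborConfig(k=5))
        same = clean.labels[graph.indices] == clean.labels[:, None]
        assert same.mean() > 0.25

    def test_mean_target_psnr_gain_at_low_snr(self):
        """k=30 averaging on a 200-image class-replicated stack: >= 5 dB gain."""
        rng = np.random.default_rng(9)
        clean_img = rng.random((32, 32)).astype(np.float32)
        clean = ImageStack(np.repeat(clean_img[None], 200, axis=0))
        noisy = add_noise(clean, SNRLevel(0.1, "low"), seed=2)
        target = neighbor_mean_stack(noisy, NeighborConfig(k=30))
        gain = psnr(clean.pixels, target.pixels).mean_db - psnr(
            clean.pixels, noisy.pixels
        ).mean_db
        assert gain >= 5.0

    def test_graph_round_trip(self, tmp_path, rng):
        stack = ImageStack(rng.random((8, 4, 4), dtype=np.float32))
        graph = nearest_neighbors(pairwise_distances(stack), NeighborConfig(k=3))
        path = tmp_path / "graph.txt"
        graph.save(path)
        loaded = NeighborGraph.load(path)
        assert np.array_equal(loaded.indices, graph.indices)
        assert np.allclose(loaded.distances, graph.distances)
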