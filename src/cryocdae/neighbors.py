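"""Neighborhood-mean pseudo-supervision targets.

Real particle stacks have no clean references, but images of nearby
orientations share their signal while their noise is independent; the pixel
mean over an image's k most similar neighbors therefore approximates a clean
target (noise variance down by ~1/k) and serves as the surrogate label
during fine-tuning. Default neighborhood size k=30 with Euclidean distance
on raw pixel vectors; correlation distance (1 - r) is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import pairwise_distances as _sk_pairwise

from .stack import ImageStack

__all__ = [
    "NeighborConfig",
    "NeighborGraph",
    "pairwise_distances",
    "nearest_neighbors",
    "mean_targets",
    "neighbor_mean_stack",
]

_METRICS = ("euclidean", "correlation")


@dataclass(frozen=True)
class NeighborConfig:
    k: int = 30
    metric: str = "euclidean"
    include_self: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")


@dataclass
class NeighborGraph:
    indices: np.ndarray  # (n, k) int
    distances: np.ndarray  # (n, k) float, non-decreasing along each row

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if self.indices.shape != self.distances.shape or self.indices.ndim != 2:
            raise ValueError("indices and distances must be parallel (n, k) arrays")

    def save(self, path) -> None:
        np.savetxt(
            path,
            np.hstack([self.indices, self.distances]),
            header=f"k={self.indices.shape[1]} columns: k neighbor indices then k distances",
        )

    @classmethod
    def load(cls, path) -> "NeighborGraph":
        raw = np.atleast_2d(np.loadtxt(path))
        k = raw.shape[1] // 2
        return cls(indices=raw[:, :k].astype(np.int64), distances=raw[:, k:])


def pairwise_distances(stack: ImageStack, metric: str = "euclidean") -> np.ndarray:
    """Symmetric n x n distance matrix on flattened pixel vectors."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    flat = stack.pixels.reshape(len(stack), -1).astype(np.float64)
    if len(stack) < 2:
        raise ValueError("need at least two images for pairwise distances")
    if metric == "correlation":
        if np.any(flat.std(axis=1) == 0):
            raise ValueError("correlation distance is undefined for constant images")
    dist = _sk_pairwise(flat, metric=metric)
    dist = 0.5 * (dist + dist.T)  # enforce exact symmetry
    np.fill_diagonal(dist, 0.0)
    return dist


def nearest_neighbors(dist: np.ndarray, cfg: NeighborConfig) -> NeighborGraph:
    """Per image, the k smallest-distance neighbors; ties break to lower index."""
    dist = np.asarray(dist, dtype=np.float64)
    n = dist.shape[0]
    limit = n if cfg.include_self else n - 1
    if cfg.k > limit:
        raise ValueError(f"k={cfg.k} out of range for {n} images (include_self={cfg.include_self})")
    work = dist.copy()
    if not cfg.include_self:
        np.fill_diagonal(work, np.inf)
    order = np.argsort(work, axis=1, kind="stable")[:, : cfg.k]
    return NeighborGraph(indices=order, distances=np.take_along_axis(work, order, axis=1))


def mean_targets(stack: ImageStack, graph: NeighborGraph) -> ImageStack:
    """Image i of the result = pixel mean of the stack over i's neighbors."""
    if graph.indices.shape[0] != len(stack) or graph.indices.max(initial=-1) >= len(stack):
        raise ValueError("neighbor graph was not built on this stack")
    means = stack.pixels[graph.indices].mean(axis=1)
    return stack.with_pixels(means)


def neighbor_mean_stack(stack: ImageStack, cfg: NeighborConfig = NeighborConfig()) -> ImageStack:
    """Convenience: distances -> kNN graph -> neighborhood-mean targets."""
    graph = nearest_neighbors(pairwise_distances(stack, cfg.metric), cfg)
    return mean_targets(stack, graph)
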