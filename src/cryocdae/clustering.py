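"""Clustering of particle stacks by orientation, scored against true classes.

Unsupervised cluster indices are arbitrary, so before computing Precision /
Recall / F1 the clusters are matched one-to-one to the ground-truth classes
by the assignment that maximizes the number of correctly placed images
(Hungarian algorithm on the contingency table, zero-padded when the cluster
and class counts differ). Per-class scores come from the matched table;
macro averages are unweighted class means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering, KMeans

from .stack import ImageStack

__all__ = [
    "ClusterAssignment",
    "ClusteringReport",
    "cluster_stack",
    "match_clusters",
    "score",
    "evaluate_clustering",
]

_METHODS = ("kmeans", "hierarchical")


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    K: int
    method: str
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.K:
            raise ValueError("cluster indices out of range")


@dataclass
class ClusteringReport:
    mapping: dict[int, int]  # cluster index -> class index
    per_class: pd.DataFrame  # columns: class, precision, recall, f1
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        macro = pd.DataFrame(
            [
                {
                    "class": "macro",
                    "precision": self.macro_precision,
                    "recall": self.macro_recall,
                    "f1": self.macro_f1,
                }
            ]
        )
        return pd.concat([self.per_class, macro], ignore_index=True)


def cluster_stack(stack, K: int, method: str = "kmeans", seed: int = 0) -> ClusterAssignment:
    """K-means (seeded) or Ward-linkage agglomerative clustering on pixels."""
    pixels = stack.pixels if isinstance(stack, ImageStack) else np.asarray(stack)
    flat = pixels.reshape(len(pixels), -1).astype(np.float64)
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if K > len(flat):
        raise ValueError(f"K={K} exceeds stack size {len(flat)}")
    if method == "kmeans":
        model = KMeans(n_clusters=K, n_init=10, max_iter=300, random_state=seed)
        labels = model.fit_predict(flat)
    else:
        labels = AgglomerativeClustering(n_clusters=K, linkage="ward").fit_predict(flat)
    return ClusterAssignment(labels=labels, K=K, method=method, seed=seed)


def contingency_table(assign: ClusterAssignment, truth: np.ndarray) -> np.ndarray:
    """Square (padded) cluster x class count table."""
    truth = np.asarray(truth, dtype=np.int64)
    if len(truth) != len(assign.labels):
        raise ValueError("label counts differ")
    n_classes = int(truth.max()) + 1
    size = max(assign.K, n_classes)
    table = np.zeros((size, size), dtype=np.int64)
    np.add.at(table, (assign.labels, truth), 1)
    return table


def match_clusters(assign: ClusterAssignment, truth: np.ndarray) -> dict[int, int]:
    """One-to-one cluster->class mapping maximizing correctly placed images."""
    table = contingency_table(assign, truth)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return {int(r): int(c) for r, c in zip(rows, cols) if r < assign.K}


def score(assign: ClusterAssignment, truth: np.ndarray, mapping: dict[int, int]) -> ClusteringReport:
    """Per-class precision/recall/F1 over matched memberships, plus macros.

    For class c matched to cluster g: TP = images of class c in cluster g,
    FP = other images in g, FN = class-c images elsewhere. A class with no
    matched cluster (or an empty one) scores precision 0.
    """
    truth = np.asarray(truth, dtype=np.int64)
    if len(truth) != len(assign.labels):
        raise ValueError("label counts differ")
    table = contingency_table(assign, truth)
    n_classes = int(truth.max()) + 1
    class_of = {c: g for g, c in mapping.items()}  # class -> matched cluster
    rows = []
    for c in range(n_classes):
        g = class_of.get(c)
        tp = int(table[g, c]) if g is not None else 0
        cluster_size = int(table[g].sum()) if g is not None else 0
        class_size = int(table[:, c].sum())
        precision = tp / cluster_size if cluster_size else 0.0
        recall = tp / class_size if class_size else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        rows.append({"class": c, "precision": precision, "recall": recall, "f1": f1})
    per_class = pd.DataFrame(rows)
    correct = sum(
        int(table[g, c]) for c, g in class_of.items() if g is not None and c < n_classes
    )
    return ClusteringReport(
        mapping=dict(mapping),
        per_class=per_class,
        macro_precision=float(per_class["precision"].mean()),
        macro_recall=float(per_class["recall"].mean()),
        macro_f1=float(per_class["f1"].mean()),
        accuracy=correct / len(truth),
    )


def evaluate_clustering(
    stack, truth: np.ndarray, K: int, method: str = "kmeans", seed: int = 0
) -> ClusteringReport:
    """Cluster, match to classes, and score in one call."""
    assign = cluster_stack(stack, K=K, method=method, seed=seed)
    return score(assign, truth, match_clusters(assign, truth))
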