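"""Greedy set-cover superclustering of a profile-similarity graph and
partitioning of trees into well-separated leaf groups via a seeded 2-D
embedding plus density clustering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import dendropy
import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .trees import mrca


@dataclass
class SimilarityGraph:
    """Undirected graph of cluster ids with hit probability and coverage."""

    nodes: set[str]
    edges: list[tuple[str, str, float, float]]  # (a, b, probability, coverage)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimilarityGraph":
        edges = [
            (str(r.a), str(r.b), float(r.probability), float(r.coverage))
            for r in df.itertuples(index=False)
        ]
        nodes = {e[0] for e in edges} | {e[1] for e in edges}
        return cls(nodes=nodes, edges=edges)


def greedy_set_cover(
    graph: SimilarityGraph,
    p_min: float = 0.8,
    cov_min: float = 0.5,
) -> list[set[str]]:
    """Supercluster by repeatedly taking the uncovered node with the
    largest uncovered neighborhood (ties lexicographic) together with its
    uncovered neighbors.  Output is a partition of the node set."""
    for threshold in (p_min, cov_min):
        if not (0.0 <= threshold <= 1.0):
            raise ValueError("thresholds must be in [0, 1]")
    adjacency: dict[str, set[str]] = {n: set() for n in graph.nodes}
    for a, b, p, cov in graph.edges:
        if a == b:
            continue
        if p >= p_min and cov >= cov_min:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
    uncovered = set(adjacency)
    clusters: list[set[str]] = []
    while uncovered:
        center = max(
            uncovered,
            key=lambda n: (len(adjacency[n] & uncovered), [-ord(c) for c in n]),
        )
        members = {center} | (adjacency[center] & uncovered)
        clusters.append(members)
        uncovered -= members
    return clusters


# ------------------------------------------------------------- tree partition


@dataclass
class TreePartition:
    assignments: dict[str, int]
    n_partitions: int
    monophyletic: dict[int, bool] = field(default_factory=dict)

    def labels(self, order: list[str]) -> np.ndarray:
        return np.array([self.assignments[leaf] for leaf in order])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignments.items()), columns=["leaf", "partition"]
        )


def classical_mds_embed(distances: np.ndarray, seed: int = 0) -> np.ndarray:
    """Deterministic 2-D classical metric scaling (sign-fixed)."""
    D2 = np.asarray(distances, dtype=float) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:2]
    coords = evecs[:, order] * np.sqrt(np.clip(evals[order], 0.0, None))
    for j in range(coords.shape[1]):
        pivot = int(np.argmax(np.abs(coords[:, j])))
        if coords[pivot, j] < 0:
            coords[:, j] *= -1
    return coords


def hdbscan_cluster(
    points: np.ndarray, seed: int = 0, min_cluster_size: int = 5
) -> np.ndarray:
    size = min(min_cluster_size, max(2, points.shape[0] // 2))
    return HDBSCAN(min_cluster_size=size, copy=True).fit_predict(points)


def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf ids (sorted) and their pairwise path-length matrix."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    ids = [l.taxon.label for l in leaves]
    # root-to-node distances plus LCA via postorder leaf sets
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    n = len(leaves)
    D = np.zeros((n, n))
    # d(a, b) = depth(a) + depth(b) - 2 * depth(lca)
    leaf_nodes = {leaf.taxon.label: leaf for leaf in leaves}
    # compute LCA depths pairwise via ancestor maps (n is small at desk scale)
    ancestors: dict[str, list] = {}
    for label, leaf in leaf_nodes.items():
        chain = []
        node = leaf
        while node is not None:
            chain.append(id(node))
            node = node.parent_node
        ancestors[label] = chain
    for i in range(n):
        set_i = set(ancestors[ids[i]])
        for j in range(i + 1, n):
            lca_id = next(a for a in ancestors[ids[j]] if a in set_i)
            d = (
                depth[id(leaf_nodes[ids[i]])]
                + depth[id(leaf_nodes[ids[j]])]
                - 2.0 * depth[lca_id]
            )
            D[i, j] = D[j, i] = d
    return ids, D


def partition_tree(
    tree: dendropy.Tree,
    embedder: Callable[[np.ndarray, int], np.ndarray] | None = None,
    clusterer: Callable[[np.ndarray, int], np.ndarray] | None = None,
    seed: int = 0,
    min_separation: float = 5.0,
) -> TreePartition:
    """Embed the patristic distance matrix to 2-D and density-cluster it.

    Noise points go to the nearest cluster centroid.  A multi-cluster
    result is only kept when clusters are well separated (smallest
    between-centroid distance at least ``min_separation`` times the
    pooled within-cluster spread); otherwise the tree stays a single
    partition, as expected for uniform pairwise-distance trees.
    Embedding failure falls back to a single partition with a warning.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 3:
        raise ValueError("need at least 3 leaves")
    embedder = embedder or classical_mds_embed
    clusterer = clusterer or hdbscan_cluster
    ids, D = patristic_matrix(tree)
    try:
        points = embedder(D, seed)
        labels = np.asarray(clusterer(points, seed))
    except Exception as exc:  # pragma: no cover - defensive fallback
        warnings.warn(f"embedding failed ({exc}); single-partition fallback")
        return TreePartition(
            assignments={i: 0 for i in ids}, n_partitions=1, monophyletic={0: True}
        )

    cluster_ids = sorted({int(l) for l in labels if l >= 0})
    if not cluster_ids:
        labels = np.zeros(len(ids), dtype=int)
        cluster_ids = [0]
    else:
        centroids = {
            c: points[labels == c].mean(axis=0) for c in cluster_ids
        }
        for i in np.where(labels < 0)[0]:
            dists = {
                c: float(np.linalg.norm(points[i] - centroid))
                for c, centroid in centroids.items()
            }
            labels[i] = min(dists, key=lambda c: (dists[c], c))
    # fuse cluster pairs that are close relative to the global spread of
    # the embedding (sub-structure inside a clade is not "well separated")
    global_rms = float(
        np.sqrt(np.mean(np.sum((points - points.mean(axis=0)) ** 2, axis=1)))
    )
    while len({int(l) for l in labels}) > 1 and global_rms > 0:
        cents = {
            c: points[labels == c].mean(axis=0)
            for c in sorted({int(l) for l in labels})
        }
        keys = list(cents)
        pairs = [
            (float(np.linalg.norm(cents[a] - cents[b])), a, b)
            for i_, a in enumerate(keys)
            for b in keys[i_ + 1 :]
        ]
        dist, a, b = min(pairs)
        if dist >= 0.25 * global_rms:
            break
        labels[labels == b] = a

    if len({int(l) for l in labels}) > 1:
        centroids = {
            c: points[labels == c].mean(axis=0)
            for c in sorted({int(l) for l in labels})
        }
        within = float(
            np.sqrt(
                np.mean(
                    [
                        np.sum((points[i] - centroids[int(labels[i])]) ** 2)
                        for i in range(len(ids))
                    ]
                )
            )
        )
        keys = list(centroids)
        sep = min(
            float(np.linalg.norm(centroids[a] - centroids[b]))
            for i_, a in enumerate(keys)
            for b in keys[i_ + 1 :]
        )
        if within > 0 and sep < min_separation * within:
            labels = np.zeros(len(ids), dtype=int)

    remap = {c: k for k, c in enumerate(sorted({int(l) for l in labels}))}
    assignments = {leaf: remap[int(l)] for leaf, l in zip(ids, labels)}

    monophyletic = {}
    for part in sorted(set(assignments.values())):
        members = {l for l, p in assignments.items() if p == part}
        node = mrca(tree, members)
        under = {leaf.taxon.label for leaf in node.leaf_iter()}
        monophyletic[part] = under == members
    return TreePartition(
        assignments=assignments,
        n_partitions=len(set(assignments.values())),
        monophyletic=monophyletic,
    )
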