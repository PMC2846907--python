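"""Minimum-spanning-tree clustering of density-equalized node coordinates.

A Euclidean MST is built over the equalized node positions; each edge gets
a Monte-Carlo p-value by comparison with edges of random MSTs over uniform
points in the same bounding region.  A long edge — longer than most null
edges — marks a statistically significant gap and gets a small p-value.
Every edge with p at or below the threshold is removed (longest first, in
one pass), and the surviving forest's connected components become node
clusters; items inherit the cluster of their best-matching node, and
single-item components are flagged as singletons/outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class MSTEdge:
    node_a: int
    node_b: int
    length: float
    p_value: float | None = None


@dataclass
class ClusterRun:
    """One pipeline iteration's discrete partition of the items."""

    item_to_cluster: np.ndarray   # (|T|,) integer labels, 0-based
    n_clusters: int
    singleton_flags: np.ndarray   # (n_clusters,) bool: exactly one item
    n_node_components: int = 0    # components of the pruned node forest
                                  # (= 1 + edges - surviving edges)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.item_to_cluster, minlength=self.n_clusters)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(coords) -> list:
    """Exact Euclidean MST by Kruskal over the complete graph.

    Ties in edge length are broken by lexicographic (node_a, node_b) order,
    making the tree deterministic; coincident nodes yield zero-length edges.
    Accepts an (m, 2) array or an EqualizedCoordinates object.
    """
    pts = np.asarray(getattr(coords, "coords", coords), dtype=float)
    m = pts.shape[0]
    if m < 2:
        raise ValueError("need at least 2 nodes for an MST")
    d = squareform(pdist(pts))
    iu = np.triu_indices(m, k=1)
    lengths = d[iu]
    order = np.lexsort((iu[1], iu[0], lengths))
    uf = _UnionFind(m)
    edges = []
    for idx in order:
        a, b = int(iu[0][idx]), int(iu[1][idx])
        if uf.union(a, b):
            edges.append(MSTEdge(a, b, float(lengths[idx])))
            if len(edges) == m - 1:
                break
    return edges


def edge_p_values(
    edges: list,
    bounding_box,
    beta: int = 10,
    seed: int = 0,
) -> list:
    """Assign Monte-Carlo p-values to MST edges.

    ``bounding_box`` is ((row_min, col_min), (row_max, col_max)).  For each
    of ``beta`` replicates, m uniform points are drawn in the box and their
    MST edge lengths pooled; p(e) is the fraction of pooled null lengths
    >= length(e), so an edge longer than every null edge has p = 0.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    m = len(edges) + 1
    (rmin, cmin), (rmax, cmax) = bounding_box
    if rmax <= rmin or cmax <= cmin:
        logger.warning("degenerate bounding box: all edge p-values set to 1")
        for e in edges:
            e.p_value = 1.0
        return edges
    rng = np.random.default_rng(seed)
    null_lengths = []
    for _ in range(beta):
        pts = rng.uniform(size=(m, 2))
        pts[:, 0] = rmin + pts[:, 0] * (rmax - rmin)
        pts[:, 1] = cmin + pts[:, 1] * (cmax - cmin)
        null_lengths.extend(e.length for e in build_mst(pts))
    null = np.sort(null_lengths)
    total = len(null)
    for e in edges:
        # count of null lengths >= e.length
        ge = total - np.searchsorted(null, e.length, side="left")
        e.p_value = ge / total
    return edges


def bounding_box(coords) -> tuple:
    pts = np.asarray(getattr(coords, "coords", coords), dtype=float)
    return (tuple(pts.min(axis=0)), tuple(pts.max(axis=0)))


def prune_and_cluster(
    edges: list,
    items_to_nodes: np.ndarray,
    p_threshold: float = 0.1,
) -> ClusterRun:
    """Cut significant edges and map node components back onto the items.

    The removal set is every edge with p <= ``p_threshold`` (processed in a
    single pass; longest-first order does not change the surviving forest).
    Components holding no items are ignored; clusters are numbered by first
    item appearance and single-item clusters flagged as singletons.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError("p_threshold must be in (0, 1]")
    if any(e.p_value is None for e in edges):
        raise ValueError("edges need p-values; run edge_p_values first")
    items_to_nodes = np.asarray(items_to_nodes)
    m = len(edges) + 1
    uf = _UnionFind(m)
    surviving = 0
    for e in sorted(edges, key=lambda e: -e.length):
        if e.p_value > p_threshold:
            uf.union(e.node_a, e.node_b)
            surviving += 1
    roots = np.array([uf.find(j) for j in range(m)])
    n_node_components = 1 + len(edges) - surviving

    labels = np.empty(len(items_to_nodes), dtype=int)
    root_to_cluster: dict = {}
    for i, node in enumerate(items_to_nodes):
        r = roots[int(node)]
        if r not in root_to_cluster:
            root_to_cluster[r] = len(root_to_cluster)
        labels[i] = root_to_cluster[r]
    n_clusters = len(root_to_cluster)
    sizes = np.bincount(labels, minlength=n_clusters)
    return ClusterRun(item_to_cluster=labels, n_clusters=n_clusters,
                      singleton_flags=sizes == 1,
                      n_node_components=n_node_components)


def major_cluster_count(run: ClusterRun, min_fraction: float = 0.05) -> int:
    """Number of clusters holding at least ``min_fraction`` of the items."""
    sizes = run.cluster_sizes()
    return int((sizes >= min_fraction * len(run.item_to_cluster)).sum())
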