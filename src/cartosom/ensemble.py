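"""Ensemble averaging of repeated map-train/equalize/cut runs.

The stochastic initialization of the node lattice makes any single run
noisy; running the pipeline E times and merging the partitions yields a
fuzzy clustering matrix F (|T| rows, one column per consensus cluster,
rows summing to E), which is resolved by sending every item to the
cluster it occupied most often.  The same runs give a per-item confidence
(percentage of runs agreeing with the final assignment) and a pairwise
affinity matrix (fraction of runs co-clustering each pair), the edge
weights of fuzzy cluster networks.

How runs are merged into consensus clusters is the method's central
interpretation point (see the methods note).  The default ("affinity")
resolution derives consensus clusters from majority co-clustering:
connected components of the graph linking pairs that share a cluster in
at least half the runs.  A single map run fragments elongated or
non-convex clusters (a ring cannot be embedded in the planar lattice
without folds), but the fragment boundaries move between runs while
points of different true clusters stay apart in every run, so the
majority-co-clustering graph chains each true cluster together and the
components recover it whole.  F then counts, for every item, the runs
whose containing fragment is associated with each consensus cluster, and
items are resolved to their most frequent cluster as usual.

The alternative ("matching") resolution harmonizes every run to the mean
cluster count (merging nearest-centroid pairs, splitting the largest
cluster by 2-means) and aligns columns to the first run's clusters by
greedy maximum overlap; it is retained for compact, well-separated
clusters and as the simplest reading of the averaging scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.vq import kmeans2

from .containers import ExpressionMatrix
from .som import TrainingSchedule, train_som, error_surface, map_items_to_nodes
from .cartogram import build_density_grid, density_equalize
from .mstcluster import (ClusterRun, build_mst, edge_p_values, bounding_box,
                         prune_and_cluster)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of one map-train/equalize/cut iteration."""

    topology: str = "square"
    min_grid: int = 5
    max_grid: int = 20
    grid_policy: str = "liberal"
    iterations: int = 1000
    theta: float = 1.5
    alpha: float = 3.0
    resolution: int = 64
    beta: int = 10
    p_threshold: float = 0.1
    connectivity: int = 8

    def schedule(self) -> TrainingSchedule:
        return TrainingSchedule(iterations=self.iterations)


@dataclass
class EnsembleResult:
    runs: list                      # E ClusterRun objects (unharmonized labels)
    mu: int                         # harmonized cluster count (mean over runs)
    F: np.ndarray                   # (|T|, mu) fuzzy membership counts
    final_labels: np.ndarray        # (|T|,) ints; -1 once confidence-filtered
    confidence: np.ndarray          # (|T|,) in [0, 100]
    affinity: np.ndarray            # (|T|, |T|) in [0, 1]
    item_ids: list = field(default_factory=list)

    @property
    def n_ensemble(self) -> int:
        return len(self.runs)

    @property
    def n_clusters(self) -> int:
        return int(self.final_labels[self.final_labels >= 0].max() + 1) \
            if (self.final_labels >= 0).any() else 0


def single_run(matrix: ExpressionMatrix, config: PipelineConfig, seed: int) -> ClusterRun:
    """One full pipeline iteration: train, error surface, equalize, cut."""
    state = train_som(matrix, config.schedule(), topology=config.topology,
                      seed=seed, min_grid=config.min_grid, max_grid=config.max_grid,
                      grid_policy=config.grid_policy)
    surface = error_surface(state, theta=config.theta, alpha=config.alpha,
                            connectivity=config.connectivity)
    grid = build_density_grid(state, surface, resolution=config.resolution)
    eq = density_equalize(grid)
    edges = build_mst(eq)
    edges = edge_p_values(edges, bounding_box(eq), beta=config.beta, seed=seed + 1)
    bmu = map_items_to_nodes(state, matrix)
    return prune_and_cluster(edges, bmu, p_threshold=config.p_threshold)


# ---------------------------------------------------------------------------
# merging runs


def _centroids(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    cents = np.empty((k, X.shape[1]))
    for j in range(k):
        cents[j] = X[labels == j].mean(axis=0)
    return cents


def _merge_once(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Merge the two clusters with nearest centroids; relabel compactly."""
    cents = _centroids(X, labels, k)
    best = None
    for a in range(k):
        for b in range(a + 1, k):
            d = np.linalg.norm(cents[a] - cents[b])
            if best is None or d < best[0]:
                best = (d, a, b)
    _, a, b = best
    labels = labels.copy()
    labels[labels == b] = a
    labels[labels > b] -= 1
    return labels


def _split_once(X: np.ndarray, labels: np.ndarray, k: int, rng) -> np.ndarray:
    """Split the largest (>= 2 item) cluster by 2-means."""
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes)
    target = next((int(j) for j in order if sizes[j] >= 2), None)
    if target is None:
        logger.warning("no splittable cluster; harmonization stops short")
        return labels
    idx = np.where(labels == target)[0]
    pts = X[idx]
    if np.allclose(pts, pts[0]):
        # identical points: split arbitrarily but deterministically in half
        sub = (np.arange(len(idx)) >= len(idx) / 2).astype(int)
    else:
        _, sub = kmeans2(pts, 2, minit="++", seed=rng)
        if len(np.unique(sub)) < 2:  # degenerate 2-means: force a median split
            proj = pts @ (pts.var(axis=0) + 1.0)
            sub = (proj > np.median(proj)).astype(int)
    labels = labels.copy()
    labels[idx[sub == 1]] = k
    return labels


def harmonize_cluster_counts(runs: list, matrix: ExpressionMatrix,
                             seed: int = 0) -> tuple:
    """Adjust every run's partition to the mean cluster count mu.

    Returns (list of label arrays with mu clusters each, mu).  mu is the
    half-up rounded mean of the per-run cluster counts.
    """
    if not runs:
        raise ValueError("need at least one run")
    X = np.asarray(matrix.values, dtype=float)
    counts = [r.n_clusters for r in runs]
    mu = int(np.floor(np.mean(counts) + 0.5))
    mu = max(mu, 1)
    rng = np.random.default_rng(seed)
    out = []
    for r in runs:
        labels = r.item_to_cluster.copy()
        k = r.n_clusters
        while k > mu:
            labels = _merge_once(X, labels, k)
            k -= 1
        while k < mu:
            new = _split_once(X, labels, k, rng)
            if new.max() + 1 == k:  # could not split further
                break
            labels = new
            k += 1
        out.append(labels)
    return out, mu


def build_fuzzy_matrix(harmonized: list, mu: int) -> np.ndarray:
    """Accumulate run partitions into the fuzzy matrix F (|T| x mu).

    Each run's clusters are matched to the first run's clusters by greedy
    maximum overlap (ties to the lower column id); F[x, j] counts the runs
    placing item x in consensus cluster j, so rows sum to the run count.
    """
    ref = harmonized[0]
    n = len(ref)
    F = np.zeros((n, mu))
    for labels in harmonized:
        k = int(labels.max()) + 1
        overlap = np.zeros((k, mu))
        for j in range(k):
            members = labels == j
            for c in range(mu):
                overlap[j, c] = np.sum(members & (ref == c))
        col_of = np.full(k, -1, dtype=int)
        used_rows, used_cols = set(), set()
        flat = sorted(
            ((overlap[j, c], j, c) for j in range(k) for c in range(mu)),
            key=lambda t: (-t[0], t[2], t[1]),
        )
        for _, j, c in flat:
            if j in used_rows or c in used_cols:
                continue
            col_of[j] = c
            used_rows.add(j)
            used_cols.add(c)
        remaining = [c for c in range(mu) if c not in used_cols]
        for j in range(k):
            if col_of[j] < 0:
                col_of[j] = remaining.pop(0)
        F[np.arange(n), col_of[labels]] += 1
    return F


def resolve(F: np.ndarray, n_runs: int) -> tuple:
    """Resolve the fuzzy matrix into labels and confidences.

    Final label = most frequent cluster (ties to the lower column id);
    confidence = 100 * F[x, label] / E.  Empty final clusters are dropped
    and labels compacted.
    """
    labels = F.argmax(axis=1)
    conf = 100.0 * F[np.arange(len(labels)), labels] / n_runs
    # compact: renumber surviving columns in ascending column order
    present = np.unique(labels)
    remap = {int(c): i for i, c in enumerate(present)}
    labels = np.array([remap[int(c)] for c in labels])
    return labels, conf


def consensus_components(affinity: np.ndarray, min_affinity: float = 0.5) -> np.ndarray:
    """Connected components of the majority-co-clustering graph.

    Two items are linked when their pairwise affinity is at least
    ``min_affinity`` (default: co-clustered in half the runs).  Component
    labels are numbered by first item appearance.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = csr_matrix(affinity >= min_affinity)
    _, comp = connected_components(adj, directed=False)
    # renumber by first appearance for determinism
    order = {}
    out = np.empty_like(comp)
    for i, c in enumerate(comp):
        if c not in order:
            order[c] = len(order)
        out[i] = order[c]
    return out


def build_consensus_fuzzy(runs: list, components: np.ndarray) -> np.ndarray:
    """Fuzzy matrix over consensus clusters.

    For every run and every run-cluster, the cluster is associated with
    the consensus component holding the plurality of its members (ties to
    the lower component id); each member then gets one count in that
    column.  Rows sum to the number of runs.
    """
    n = len(components)
    k = int(components.max()) + 1
    F = np.zeros((n, k))
    for r in runs:
        labels = r.item_to_cluster
        for c in range(r.n_clusters):
            members = np.where(labels == c)[0]
            counts = np.bincount(components[members], minlength=k)
            target = int(counts.argmax())
            F[members, target] += 1
    return F


def pairwise_affinity(runs: list) -> np.ndarray:
    """Fraction of runs in which each pair of items co-clusters.

    Computed on the raw per-run labels (before harmonization); symmetric
    with a unit diagonal.
    """
    if not runs:
        raise ValueError("need at least one run")
    n = len(runs[0].item_to_cluster)
    aff = np.zeros((n, n))
    for r in runs:
        lab = r.item_to_cluster
        aff += (lab[:, None] == lab[None, :])
    aff /= len(runs)
    np.fill_diagonal(aff, 1.0)
    return aff


def run_ensemble(
    matrix: ExpressionMatrix,
    config: PipelineConfig | None = None,
    n_ensemble: int = 50,
    seed: int = 0,
    consensus: str = "affinity",
    min_affinity: float = 0.5,
) -> EnsembleResult:
    """Run the pipeline ``n_ensemble`` times and merge the partitions.

    ``consensus`` selects how runs are merged: "affinity" (default)
    resolves items into connected components of the majority
    co-clustering graph, "matching" harmonizes runs to the mean cluster
    count and aligns them by greedy maximum overlap.  Per-run seeds are
    derived as seed + 1000 * run_index, so the result is deterministic
    given the master seed while each run still starts from its own random
    lattice.
    """
    if n_ensemble < 1:
        raise ValueError("n_ensemble must be >= 1")
    if consensus not in ("affinity", "matching"):
        raise ValueError(f"unknown consensus scheme {consensus!r}")
    if config is None:
        config = PipelineConfig()
    runs = []
    for i in range(n_ensemble):
        try:
            runs.append(single_run(matrix, config, seed=seed + 1000 * i))
        except Exception as exc:
            raise RuntimeError(f"ensemble run {i} failed: {exc}") from exc
    aff = pairwise_affinity(runs)
    mu = int(np.floor(np.mean([r.n_clusters for r in runs]) + 0.5))
    if consensus == "affinity":
        comp = consensus_components(aff, min_affinity=min_affinity)
        F = build_consensus_fuzzy(runs, comp)
    else:
        harmonized, mu = harmonize_cluster_counts(runs, matrix, seed=seed)
        F = build_fuzzy_matrix(harmonized, mu)
    labels, conf = resolve(F, n_ensemble)
    return EnsembleResult(runs=runs, mu=mu, F=F, final_labels=labels,
                          confidence=conf, affinity=aff,
                          item_ids=list(matrix.item_ids))


def filter_by_confidence(result: EnsembleResult, min_conf: float) -> EnsembleResult:
    """Mark items with confidence below ``min_conf`` as unassigned (-1).

    Filtered items are excluded from cluster outputs but keep their rows
    in the affinity matrix.
    """
    if not (0.0 <= min_conf <= 100.0):
        raise ValueError("min_conf must be in [0, 100]")
    labels = result.final_labels.copy()
    labels[result.confidence < min_conf] = -1
    return EnsembleResult(runs=result.runs, mu=result.mu, F=result.F,
                          final_labels=labels, confidence=result.confidence.copy(),
                          affinity=result.affinity, item_ids=list(result.item_ids))
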