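"""Two-phase Kohonen self-organizing map with error-surface computation.

The map is a 2-D lattice of weight-vector nodes, square by default or
circular (the square lattice with corner nodes outside the inscribed disc
removed).  Training draws random items over two phases — a coarse
organization phase and a fine-tuning phase — with exponentially decaying
learning rate and Gaussian neighbourhood radius in each phase.

The per-node error surface En (a U-matrix analogue) quantifies
dissimilarity to adjacent nodes: high values mark cluster boundaries.  It
is softened by an exponent 1/theta (theta > 1 deflates the contribution of
large neighbour distances, damping outlier nodes), max-normalized to [0, 1]
and raised to a cubic power alpha to accentuate separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .containers import ExpressionMatrix

TOPOLOGIES = ("square", "circular")


@dataclass
class TrainingSchedule:
    """Two-phase training parameters.

    ``iterations`` items are presented per phase.  Learning rates start at
    0.9 (organization) and 0.1 (fine tuning); the neighbourhood radius
    starts at half and a quarter of the grid width respectively.  Within a
    phase both decay exponentially — the radius to 1 lattice unit and the
    learning rate by ``learn_decay``.
    """

    iterations: int = 1000
    learn_phase1: float = 0.9
    learn_phase2: float = 0.1
    radius_frac_phase1: float = 0.5
    radius_frac_phase2: float = 0.25
    learn_decay: float = 0.1

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class SOMState:
    """A trained (or initialized) node lattice."""

    weights: np.ndarray          # (m, d) node feature vectors
    grid_coords: np.ndarray      # (m, 2) integer lattice (row, col), 0-based
    topology: str = "square"
    side: int = 0                # lattice side length before any circular mask
    rng_seed: int = 0

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def neighbor_lists(self, connectivity: int = 8) -> list:
        """Indices of directly adjacent nodes for every node.

        ``connectivity`` is 8 (default, includes diagonals) or 4.
        """
        if connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        coords = self.grid_coords
        index = {(int(r), int(c)): j for j, (r, c) in enumerate(coords)}
        if connectivity == 8:
            offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                       (0, 1), (1, -1), (1, 0), (1, 1)]
        else:
            offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
        out = []
        for r, c in coords:
            nbrs = [index[(int(r) + dr, int(c) + dc)] for dr, dc in offsets
                    if (int(r) + dr, int(c) + dc) in index]
            out.append(nbrs)
        return out


@dataclass
class ErrorSurface:
    """Per-node boundary score En in [0, 1] after softening and rescaling."""

    En: np.ndarray
    theta: float = 1.5
    alpha: float = 3.0


def auto_grid_size(n_items: int, min_grid: int = 5, max_grid: int = 20) -> int:
    """Side length of the square lattice for ``n_items`` input items.

    Uses the ~5*sqrt(N) total-node heuristic, i.e.
    side = ceil(sqrt(5 * sqrt(n_items))), clamped to [min_grid, max_grid].
    """
    if min_grid > max_grid:
        raise ValueError(f"min_grid {min_grid} > max_grid {max_grid}")
    if n_items < 2:
        raise ValueError("need at least 2 items")
    side = math.ceil(math.sqrt(5.0 * math.sqrt(n_items)))
    return int(min(max(side, min_grid), max_grid))


def liberal_grid_size(n_items: int, min_grid: int = 5, max_grid: int = 20) -> int:
    """Side length under liberal node allocation (about one node per item).

    side = ceil(sqrt(n_items)), clamped to [min_grid, max_grid].  Liberal
    allocation keeps boundary detection sharp: with roughly as many nodes
    as items, nodes that interpolate across empty regions between clusters
    are few and carry large weight jumps, so the error surface develops
    the contrast the downstream density equalization needs.  This is the
    pipeline default; the sparser ~5*sqrt(N) rule of
    :func:`auto_grid_size` is available for memory-constrained runs.
    """
    if min_grid > max_grid:
        raise ValueError(f"min_grid {min_grid} > max_grid {max_grid}")
    if n_items < 2:
        raise ValueError("need at least 2 items")
    side = math.ceil(math.sqrt(n_items))
    return int(min(max(side, min_grid), max_grid))


_GRID_POLICIES = {"liberal": liberal_grid_size, "heuristic": auto_grid_size}


def make_lattice(side: int, topology: str = "square") -> np.ndarray:
    """Integer (row, col) coordinates of the lattice nodes.

    Circular topology keeps only nodes inside the disc inscribed in the
    square lattice.
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()])
    if topology == "circular":
        center = (side - 1) / 2.0
        rad = side / 2.0
        keep = ((coords[:, 0] - center) ** 2 + (coords[:, 1] - center) ** 2) <= rad ** 2
        coords = coords[keep]
    return coords


def train_som(
    matrix: ExpressionMatrix,
    schedule: TrainingSchedule | None = None,
    topology: str = "square",
    seed: int = 0,
    min_grid: int = 5,
    max_grid: int = 20,
    grid_policy: str = "liberal",
) -> SOMState:
    """Train a map on the rows of ``matrix``; deterministic given ``seed``."""
    X = np.asarray(matrix.values, dtype=float)
    if X.size == 0:
        raise ValueError("empty input matrix")
    if schedule is None:
        schedule = TrainingSchedule()
    if grid_policy not in _GRID_POLICIES:
        raise ValueError(f"unknown grid policy {grid_policy!r}")
    n = X.shape[0]
    side = _GRID_POLICIES[grid_policy](max(n, 2), min_grid, max_grid)
    coords = make_lattice(side, topology).astype(float)
    m = coords.shape[0]

    rng = np.random.default_rng(seed)
    # initialize nodes on randomly drawn items: the untrained lattice is a
    # random scatter of data points, which keeps nodes on the data manifold
    weights = X[rng.integers(0, n, size=m)].astype(float).copy()
    if n == 1:
        weights = np.repeat(X, m, axis=0).astype(float)

    I = schedule.iterations
    phases = (
        (schedule.learn_phase1, schedule.radius_frac_phase1),
        (schedule.learn_phase2, schedule.radius_frac_phase2),
    )
    for eta0, rfrac in phases:
        r0 = max(rfrac * side, 1.0)
        # exponential decay factors precomputed per iteration
        fracs = np.arange(I) / I
        etas = eta0 * schedule.learn_decay ** fracs
        radii = r0 * (1.0 / r0) ** fracs  # decays from r0 to 1
        picks = rng.integers(0, n, size=I)
        for i in range(I):
            t = X[picks[i]]
            diff = t - weights
            winner = int(np.argmin((diff * diff).sum(axis=1)))
            lat = coords - coords[winner]
            lat_d2 = (lat * lat).sum(axis=1)
            h = np.exp(-lat_d2 / (2.0 * radii[i] ** 2))
            weights += (etas[i] * h)[:, None] * diff
    return SOMState(weights=weights, grid_coords=coords.astype(int),
                    topology=topology, side=side, rng_seed=seed)


def error_surface(
    state: SOMState,
    theta: float = 1.5,
    alpha: float = 3.0,
    connectivity: int = 8,
) -> ErrorSurface:
    """Compute the softened, cubically rescaled error surface.

    Dn_j is the mean Euclidean distance between node j's weights and each
    directly adjacent node's weights; raw_j = Dn_j^(1/theta) is divided by
    its maximum and raised to alpha.
    """
    nbrs = state.neighbor_lists(connectivity)
    W = state.weights
    Dn = np.empty(state.n_nodes)
    for j, nb in enumerate(nbrs):
        if not nb:
            raise RuntimeError(f"node {j} has no lattice neighbors")
        Dn[j] = np.linalg.norm(W[nb] - W[j], axis=1).mean()
    raw = Dn ** (1.0 / theta)
    mx = raw.max()
    if mx > 0:
        raw = raw / mx
    En = raw ** alpha
    return ErrorSurface(En=En, theta=theta, alpha=alpha)


def map_items_to_nodes(state: SOMState, matrix: ExpressionMatrix) -> np.ndarray:
    """Best-matching unit per item; ties go to the lowest node index."""
    d = cdist(np.asarray(matrix.values, dtype=float), state.weights)
    return d.argmin(axis=1)
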