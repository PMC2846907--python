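"""Synthetic benchmark datasets with known cluster structure.

Three generators cover the standard shapes used to exercise the pipeline:
well-separated 2-D Gaussian blobs (compact clusters), two orthogonal
interlocking 3-D rings (non-convex, non-linearly-separable clusters), and
the bars dataset of 6 vertical and 2 horizontal line segments (elongated
clusters of unequal size).  Every generator is deterministic given its
seed and returns (ExpressionMatrix, truth labels).

Default geometries are chosen so the nearest between-class gap exceeds
the within-class point spacing by at least 3x, making every dataset
clusterable by construction; all sizes and scales are configurable.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .containers import ExpressionMatrix


def _wrap(points: np.ndarray, labels: np.ndarray, feature_ids) -> tuple:
    ids = [f"p{i:05d}" for i in range(len(points))]
    return ExpressionMatrix(ids, list(feature_ids), points), np.asarray(labels)


def make_gaussians(
    k: int = 4,
    n: int = 100,
    sd: float = 0.5,
    separation: float = 10.0,
    seed: int = 0,
) -> tuple:
    """k isotropic 2-D Gaussian blobs of n points on a square grid of centers.

    Warns when separation < 6*sd, i.e. when adjacent blobs overlap at the
    3-sd radius.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if separation < 6 * sd:
        warnings.warn("blobs overlap at 3 sd; clusters may not be separable",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    side = math.ceil(math.sqrt(k))
    centers = np.array([(separation * (i // side), separation * (i % side))
                        for i in range(k)], dtype=float)
    pts = np.concatenate([
        centers[i] + rng.normal(scale=sd, size=(n, 2)) if sd > 0
        else np.tile(centers[i], (n, 1))
        for i in range(k)
    ])
    labels = np.repeat(np.arange(k), n)
    return _wrap(pts, labels, ["x", "y"])


def make_rings(
    n_per_ring: int = 500,
    radius: float = 1.0,
    tube_sd: float = 0.03,
    seed: int = 0,
) -> tuple:
    """Two orthogonal interlocking rings in 3-D (1000 points by default,
    the scale of the classic chain-link benchmark).

    The first ring lies in the xy-plane centered at the origin; the second
    lies in the xz-plane with its center offset by one radius along x, so
    the circles interlock like chain links and are everywhere at least one
    radius apart.  Points are uniform in angle with isotropic Gaussian
    tube noise of sd ``tube_sd``.
    """
    rng = np.random.default_rng(seed)
    th1 = rng.uniform(0, 2 * np.pi, n_per_ring)
    th2 = rng.uniform(0, 2 * np.pi, n_per_ring)
    ring1 = np.column_stack([radius * np.cos(th1), radius * np.sin(th1),
                             np.zeros(n_per_ring)])
    ring2 = np.column_stack([radius + radius * np.cos(th2),
                             np.zeros(n_per_ring), radius * np.sin(th2)])
    pts = np.concatenate([ring1, ring2])
    if tube_sd > 0:
        pts = pts + rng.normal(scale=tube_sd, size=pts.shape)
    labels = np.repeat([0, 1], n_per_ring)
    return _wrap(pts, labels, ["x", "y", "z"])


def make_bars(
    seed: int = 0,
    n_vertical: int = 100,
    n_horizontal: int = 152,
    bar_length: float = 10.0,
    spacing: float = 2.0,
) -> tuple:
    """The bars dataset: 6 evenly-spaced vertical lines (``n_vertical``
    points each) with one horizontal line above and another below
    (``n_horizontal`` points each) — 8 classes, 904 points at the defaults.
    """
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for i in range(6):
        x = np.full(n_vertical, i * spacing)
        y = rng.uniform(0, bar_length, n_vertical)
        parts.append(np.column_stack([x, y]))
        labels.append(np.full(n_vertical, i))
    x_lo, x_hi = -spacing, 5 * spacing + spacing
    gap = 3.0
    for j, y0 in enumerate([bar_length + gap, -gap]):
        x = rng.uniform(x_lo, x_hi, n_horizontal)
        y = np.full(n_horizontal, y0)
        parts.append(np.column_stack([x, y]))
        labels.append(np.full(n_horizontal, 6 + j))
    return _wrap(np.concatenate(parts), np.concatenate(labels), ["x", "y"])
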