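"""Normalizations and distance metrics applied before map training.

The normalization steps mirror common microarray practice: log2 scaling,
unit-variance scaling, median centering of genes and/or arrays, iterative
sum-of-squares normalization, and 0-100 range scaling of columns.  When
samples (transcriptomes) rather than genes are clustered, the feature matrix
is first converted to a square distance matrix and each sample is
represented by its distance profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "pearson", "uncentered")


@dataclass
class NormalizationPlan:
    """Which normalization steps to run, applied in the declared field order."""

    log2: bool = False
    unit_variance: bool = False
    median_center_genes: bool = False
    median_center_arrays: bool = False
    sum_squares_normalize: bool = False
    range_0_100: bool = False


@dataclass
class DistanceSpec:
    """Distance metric and clustering mode.

    metric: euclidean, pearson (1 - r) or uncentered (1 - r computed without
    mean subtraction, the Cluster-software convention).
    mode: ``feature_rows`` clusters the rows as-is; ``distance_matrix``
    converts rows to a square distance matrix first.
    """

    metric: str = "euclidean"
    mode: str = "feature_rows"

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.mode not in ("feature_rows", "distance_matrix"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _pop_sd(x: np.ndarray, axis: int) -> np.ndarray:
    # population convention (divide by n); documented and deliberate
    return np.std(x, axis=axis, ddof=0)


def unit_variance_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each row by its (population) standard deviation.

    Rows with zero spread are left unchanged and logged.
    """
    v = matrix.values.copy()
    sd = _pop_sd(v, axis=1)
    zero = sd == 0
    if zero.any():
        logger.info("unit_variance_rows: %d constant rows left unchanged", int(zero.sum()))
    sd_safe = np.where(zero, 1.0, sd)
    return matrix.copy_with(v / sd_safe[:, None])


def _unit_variance_cols(v: np.ndarray) -> np.ndarray:
    sd = _pop_sd(v, axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return v / sd


def _sum_squares(v: np.ndarray, tol: float = 1e-6, max_sweeps: int = 50) -> np.ndarray:
    """Alternate row/column sum-of-squares rescaling to convergence.

    For square matrices every row and column reaches unit sum of squares.
    A rectangular n x d matrix cannot satisfy both at once (the totals
    n and d disagree); the iteration then converges to the balanced fixed
    point with unit column sums of squares and all row sums equal (d/n),
    which is what repeated gene/array normalization produces in practice.
    """
    v = v.copy()
    for _ in range(max_sweeps):
        rs = np.sqrt((v ** 2).sum(axis=1))
        v = v / np.where(rs == 0, 1.0, rs)[:, None]
        cs = np.sqrt((v ** 2).sum(axis=0))
        v = v / np.where(cs == 0, 1.0, cs)[None, :]
        rs = (v ** 2).sum(axis=1)
        cs = (v ** 2).sum(axis=0)
        rs, cs = rs[rs > 0], cs[cs > 0]
        stationary = (len(rs) == 0 or np.ptp(rs) < tol) and \
                     (len(cs) == 0 or (np.abs(cs - 1) < tol).all())
        if stationary:
            break
    return v


def normalize(matrix: ExpressionMatrix, plan: NormalizationPlan,
              log2_clip: bool = False) -> ExpressionMatrix:
    """Apply the enabled steps of ``plan`` in their fixed order."""
    v = matrix.values.copy()
    if plan.log2:
        if (v <= 0).any():
            if not log2_clip:
                r, c = np.argwhere(v <= 0)[0]
                raise ValueError(
                    f"log2 on non-positive value at row {matrix.item_ids[r]!r}, "
                    f"column {matrix.feature_ids[c]!r} ({v[r, c]}); "
                    "set log2_clip to clip to the smallest positive value"
                )
            smallest = v[v > 0].min() if (v > 0).any() else 1.0
            v = np.where(v <= 0, smallest, v)
        v = np.log2(v)
    if plan.unit_variance:
        v = _unit_variance_cols(v)
    if plan.median_center_genes:
        v = v - np.median(v, axis=1)[:, None]
    if plan.median_center_arrays:
        v = v - np.median(v, axis=0)[None, :]
    if plan.sum_squares_normalize:
        v = _sum_squares(v)
    out = matrix.copy_with(v)
    if plan.range_0_100:
        out = range_normalize_columns(out)
    return out


def range_normalize_columns(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Affinely map each column onto [0, 100]; constant columns map to zero."""
    v = matrix.values.copy()
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    span = hi - lo
    const = span == 0
    span = np.where(const, 1.0, span)
    v = (v - lo) / span * 100.0
    v[:, const] = 0.0
    return matrix.copy_with(v)


def _uncentered_corr(v: np.ndarray) -> np.ndarray:
    # r = sum(x*y) / sqrt(sum(x^2) * sum(y^2)), no mean subtraction
    norms = np.sqrt((v ** 2).sum(axis=1))
    safe = np.where(norms == 0, 1.0, norms)
    u = v / safe[:, None]
    r = u @ u.T
    r[norms == 0, :] = 0.0
    r[:, norms == 0] = 0.0
    return np.clip(r, -1.0, 1.0)


def compute_distance(matrix: ExpressionMatrix, spec: DistanceSpec) -> ExpressionMatrix:
    """Convert a feature matrix into a square symmetric distance matrix.

    Correlation distances are 1 - r; a zero-variance row under the Pearson
    metric gets r = 0 (distance 1) against every partner, logged.
    """
    v = matrix.values
    if v.shape[0] < 2:
        raise ValueError("need at least 2 items for a distance matrix")
    if spec.metric == "euclidean":
        d = cdist(v, v, metric="euclidean")
    elif spec.metric == "pearson":
        sd = _pop_sd(v, axis=1)
        zero = sd == 0
        if zero.any():
            logger.warning("pearson: %d zero-variance rows get distance 1", int(zero.sum()))
        centered = v - v.mean(axis=1)[:, None]
        r = _uncentered_corr(centered)
        d = 1.0 - r
        d[zero, :] = 1.0
        d[:, zero] = 1.0
        np.fill_diagonal(d, 0.0)
    else:  # uncentered
        r = _uncentered_corr(v)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against fp noise
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return matrix.copy_with(d, is_distance=True)


def prepare_features(matrix: ExpressionMatrix, spec: DistanceSpec) -> ExpressionMatrix:
    """Return the matrix actually fed to the map trainer.

    In ``distance_matrix`` mode each item is represented by its row of the
    distance matrix (its distance profile), which preserves the conversion
    while giving the trainer fixed-dimension vectors.  A matrix already
    flagged ``is_distance`` is passed through.
    """
    if matrix.is_distance:
        return matrix
    if spec.mode == "distance_matrix":
        return compute_distance(matrix, spec)
    return matrix
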