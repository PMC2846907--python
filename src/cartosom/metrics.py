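"""External cluster-quality metrics against ground-truth labels.

Both metrics ignore unassigned items (label -1), treating filtered
outliers as absent rather than wrong.
"""

from __future__ import annotations

import numpy as np


def _validate(labels, truth):
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape or labels.ndim != 1:
        raise ValueError("labels and truth must be 1-D arrays of equal length")
    keep = labels >= 0
    return labels[keep], truth[keep]


def f_measure(labels, truth) -> float:
    """Class-weighted clustering F-measure.

    For every truth class i and cluster j, F(i, j) = 2PR/(P+R) with
    precision P = |i ∩ j|/|j| and recall R = |i ∩ j|/|i|; the score is the
    class-size-weighted sum of each class's best F over clusters.  1 is a
    perfect solution.
    """
    labels, truth = _validate(labels, truth)
    n = len(labels)
    if n == 0:
        raise ValueError("no assigned items")
    classes, truth_idx = np.unique(truth, return_inverse=True)
    clusters, lab_idx = np.unique(labels, return_inverse=True)
    cont = np.zeros((len(classes), len(clusters)))
    np.add.at(cont, (truth_idx, lab_idx), 1)
    class_sizes = cont.sum(axis=1)
    cluster_sizes = cont.sum(axis=0)
    P = cont / cluster_sizes[None, :]
    R = cont / class_sizes[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(P + R > 0, 2 * P * R / (P + R), 0.0)
    return float(np.sum(class_sizes / n * F.max(axis=1)))


def nmi(labels, truth, average: str = "geometric") -> float:
    """Normalized mutual information between two partitions.

    I(labels; truth) divided by the geometric (default) or arithmetic mean
    of the two entropies; defined as 1 when both partitions are trivial
    (zero entropy) and 0 when only one is.
    """
    if average not in ("geometric", "arithmetic"):
        raise ValueError("average must be 'geometric' or 'arithmetic'")
    labels, truth = _validate(labels, truth)
    n = len(labels)
    if n == 0:
        raise ValueError("no assigned items")
    _, ti = np.unique(truth, return_inverse=True)
    _, li = np.unique(labels, return_inverse=True)
    cont = np.zeros((ti.max() + 1, li.max() + 1))
    np.add.at(cont, (ti, li), 1)
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    mi = np.sum(pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz]))
    hi = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
    hj = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
    if hi == 0 and hj == 0:
        return 1.0
    denom = np.sqrt(hi * hj) if average == "geometric" else (hi + hj) / 2
    if denom == 0:
        return 0.0
    return float(np.clip(mi / denom, 0.0, 1.0))
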