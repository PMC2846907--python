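"""Estimator-style facade over the full clustering pipeline.

``SOMEnsemble`` is built from data (an ExpressionMatrix, a DataFrame or a
plain array) plus the pipeline parameters; ``fit`` runs preprocessing and
the ensemble and returns a ``SOMEnsembleResults`` object carrying the
final partition, per-item confidences, the fuzzy membership matrix and
pairwise affinities, with ``summary()`` and plotting helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from . import io as _io
from .preprocess import (NormalizationPlan, DistanceSpec, normalize,
                         unit_variance_rows, prepare_features)
from .ensemble import (PipelineConfig, EnsembleResult, run_ensemble,
                       filter_by_confidence)
from .mstcluster import major_cluster_count
from . import metrics as _metrics


class SOMEnsemble:
    """Unsupervised clustering model for a labelled feature matrix.

    Parameters
    ----------
    data : ExpressionMatrix, DataFrame or array-like
        Items in rows, features in columns.
    mode : {"gene", "sample"}
        "gene" clusters the rows as feature vectors. "sample" represents
        each row by its profile of distances to all other rows (the
        transcriptome-clustering style) before training.
    metric : {"euclidean", "pearson", "uncentered"}
        Distance metric for sample mode.
    normalization : NormalizationPlan, optional
        Normalization steps applied before anything else.
    unit_variance_items : bool
        Scale each row to unit (population) variance first, the usual
        preparation for sample-mode microarray clustering.
    n_ensemble : int
        Number of pipeline iterations E merged into the result.
    confidence_min : float
        Items whose final confidence falls below this are marked
        unassigned (-1).
    Remaining keyword arguments (topology, min_grid, max_grid, iterations,
    theta, alpha, resolution, beta, p_threshold, connectivity) configure
    the per-run pipeline; see PipelineConfig.
    """

    def __init__(
        self,
        data,
        *,
        mode: str = "gene",
        metric: str = "euclidean",
        normalization: NormalizationPlan | None = None,
        unit_variance_items: bool = False,
        n_ensemble: int = 50,
        confidence_min: float = 0.0,
        **pipeline_kwargs,
    ):
        if isinstance(data, ExpressionMatrix):
            self.matrix = data
        elif isinstance(data, pd.DataFrame):
            self.matrix = ExpressionMatrix.from_dataframe(data)
        else:
            arr = np.asarray(data, dtype=float)
            self.matrix = ExpressionMatrix(
                [f"item{i}" for i in range(arr.shape[0])],
                [f"f{j}" for j in range(arr.shape[1])],
                arr,
            )
        if mode not in ("gene", "sample"):
            raise ValueError("mode must be 'gene' or 'sample'")
        self.mode = mode
        self.metric = metric
        self.normalization = normalization
        self.unit_variance_items = unit_variance_items
        self.n_ensemble = n_ensemble
        self.confidence_min = confidence_min
        self.config = PipelineConfig(**pipeline_kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SOMEnsemble":
        return cls(df, **kwargs)

    @classmethod
    def from_file(cls, path, format: str = "tabular", **kwargs) -> "SOMEnsemble":
        return cls(_io.read_table(path, format=format), **kwargs)

    def prepared_matrix(self) -> ExpressionMatrix:
        """The matrix actually fed to the trainer after preprocessing."""
        mat = self.matrix
        if self.normalization is not None:
            mat = normalize(mat, self.normalization)
        if self.unit_variance_items:
            mat = unit_variance_rows(mat)
        spec = DistanceSpec(
            metric=self.metric,
            mode="distance_matrix" if self.mode == "sample" else "feature_rows",
        )
        return prepare_features(mat, spec)

    def fit(self, seed: int = 0) -> "SOMEnsembleResults":
        prepared = self.prepared_matrix()
        result = run_ensemble(prepared, self.config,
                              n_ensemble=self.n_ensemble, seed=seed)
        if self.confidence_min > 0:
            result = filter_by_confidence(result, self.confidence_min)
        return SOMEnsembleResults(self, result, seed=seed)


class SOMEnsembleResults:
    """Fitted ensemble clustering: partition, confidences, affinities."""

    def __init__(self, model: SOMEnsemble, result: EnsembleResult, seed: int = 0):
        self.model = model
        self.ensemble = result
        self.seed = seed
        self.labels_ = result.final_labels
        self.confidence_ = result.confidence
        self.affinity_ = result.affinity
        self.fuzzy_ = result.F
        self.mu_ = result.mu

    @property
    def n_clusters(self) -> int:
        return self.ensemble.n_clusters

    def major_cluster_counts(self, min_fraction: float = 0.05) -> int:
        """Number of final clusters holding >= ``min_fraction`` of items."""
        assigned = self.labels_ >= 0
        sizes = np.bincount(self.labels_[assigned])
        return int((sizes >= min_fraction * assigned.sum()).sum())

    def cluster_sizes(self) -> pd.Series:
        assigned = self.labels_[self.labels_ >= 0]
        return pd.Series(assigned).value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "item_id": self.ensemble.item_ids,
            "cluster": self.labels_,
            "confidence": self.confidence_,
        })

    def score(self, truth, kind: str = "f_measure") -> float:
        """Cluster quality against ground-truth labels."""
        fn = {"f_measure": _metrics.f_measure, "nmi": _metrics.nmi}[kind]
        return fn(self.labels_, truth)

    def write(self, out_prefix) -> dict:
        """Write assignment/edge/heat-map tables; see io.write_outputs."""
        return _io.write_outputs(self.ensemble, self.model.matrix, out_prefix)

    def summary(self) -> str:
        sizes = self.cluster_sizes()
        singletons = int((sizes == 1).sum())
        lines = [
            "SOM ensemble clustering results",
            "===============================",
            f"items                {len(self.labels_)}",
            f"ensemble runs (E)    {self.ensemble.n_ensemble}",
            f"mean clusters (mu)   {self.mu_}",
            f"final clusters       {self.n_clusters}",
            f"major clusters (>=5%) {self.major_cluster_counts()}",
            f"singleton clusters   {singletons}",
            f"unassigned items     {int((self.labels_ < 0).sum())}",
            f"mean confidence      {self.confidence_.mean():.1f}",
            "",
            "cluster sizes:",
        ]
        for cl, size in sizes.items():
            lines.append(f"  cluster {cl:3d}  {int(size):6d} items")
        return "\n".join(lines)

    def plot_affinity(self, ax=None):
        """Heat map of the pairwise affinity matrix, rows ordered by cluster."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        order = np.lexsort((np.arange(len(self.labels_)), self.labels_))
        im = ax.imshow(self.affinity_[np.ix_(order, order)], cmap="viridis",
                       vmin=0, vmax=1, interpolation="nearest")
        ax.set_xlabel("items (cluster order)")
        ax.set_ylabel("items (cluster order)")
        ax.figure.colorbar(im, ax=ax, label="pairwise affinity")
        return ax

    def plot_confidence(self, ax=None):
        """Histogram of per-item confidence values."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.confidence_, bins=20, range=(0, 100))
        ax.set_xlabel("confidence (%)")
        ax.set_ylabel("items")
        return ax
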