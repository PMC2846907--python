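"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """A labelled numeric matrix of items (rows) by features (columns).

    The container covers both ordinary feature matrices (|T| items of
    dimensionality d) and precomputed square distance matrices used for
    sample-mode clustering, flagged by ``is_distance``.

    Parameters
    ----------
    item_ids : list of str
        Row labels, one per item, in file/input order.
    feature_ids : list of str
        Column labels.
    values : ndarray of shape (n_items, n_features)
        Numeric values; never contains NaN after loading.
    is_distance : bool
        True when ``values`` is a square symmetric distance matrix with a
        zero diagonal.
    """

    item_ids: list = field(default_factory=list)
    feature_ids: list = field(default_factory=list)
    values: np.ndarray = None
    is_distance: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.item_ids) != n:
            raise ValueError(f"{len(self.item_ids)} item ids for {n} rows")
        if len(self.feature_ids) != d:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {d} columns")
        if np.isnan(self.values).any():
            raise ValueError("matrix contains NaN after load")
        if self.is_distance:
            if n != d:
                raise ValueError("distance matrix must be square")
            if not np.allclose(self.values, self.values.T, atol=1e-9):
                raise ValueError("distance matrix must be symmetric within 1e-9")
            if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
                raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, is_distance: bool = False) -> "ExpressionMatrix":
        return cls(
            item_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            is_distance=is_distance,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.item_ids, columns=self.feature_ids)

    def copy_with(self, values: np.ndarray, is_distance: bool | None = None) -> "ExpressionMatrix":
        """Return a copy sharing labels but holding new ``values``."""
        if is_distance is None:
            is_distance = self.is_distance
        ids = self.item_ids
        cols = self.feature_ids
        if is_distance and not self.is_distance:
            cols = list(ids)
        return ExpressionMatrix(list(ids), list(cols), np.array(values, dtype=float), is_distance)
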