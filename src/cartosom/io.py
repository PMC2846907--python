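"""Readers and writers for expression matrices and clustering outputs.

Supported input dialects:

* plain tab-delimited text (header row of feature names, first column = ids),
* PCL, the Cluster-software "Pre-CLuster" dialect, whose NAME/GWEIGHT columns
  and EWEIGHT row are annotation rather than data,
* GEO series-matrix text, where only the block between
  ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` is a table.

Outputs are Cytoscape-importable TSV tables: a per-item cluster assignment
table, a pairwise-affinity edge table and a cluster-reordered matrix for
heat maps.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

FORMATS = ("tabular", "pcl", "geo_series_matrix")

_PCL_META_COLS = {"name", "gweight"}
_PCL_META_ROWS = {"eweight"}


class FormatError(ValueError):
    """Raised when a file does not match the declared dialect."""


def _dedupe_or_collapse(df: pd.DataFrame, collapse_duplicates: str | None) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    if collapse_duplicates == "mean":
        logger.info("collapsing %d duplicate row ids by mean", df.index.duplicated().sum())
        return df.groupby(level=0, sort=False).mean()
    # make unique by suffixing .1, .2, ...
    counts: dict = {}
    new_index = []
    for name in df.index:
        k = counts.get(name, 0)
        new_index.append(name if k == 0 else f"{name}.{k}")
        counts[name] = k + 1
    out = df.copy()
    out.index = new_index
    logger.warning("duplicate row ids made unique by suffixing")
    return out


def _impute_missing(df: pd.DataFrame) -> pd.DataFrame:
    """Row-mean imputation; rows that are entirely missing are dropped."""
    if not df.isna().any().any():
        return df
    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        logger.warning("dropping %d entirely-missing rows", int(all_missing.sum()))
        df = df.loc[~all_missing]
    row_means = df.mean(axis=1)
    return df.apply(lambda col: col.fillna(row_means))


def _read_tsv_block(text: str, path: str) -> pd.DataFrame:
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: empty table")
    header = lines[0].split("\t")
    width = len(header)
    rows, index = [], []
    for i, ln in enumerate(lines[1:], start=1):
        parts = ln.split("\t")
        if len(parts) != width:
            raise FormatError(
                f"{path}: ragged row {i}: {len(parts)} fields, header has {width}"
            )
        index.append(parts[0].strip().strip('"'))
        rows.append(parts[1:])
    cols = [c.strip().strip('"') for c in header[1:]]
    df = pd.DataFrame(rows, index=index, columns=cols)
    df = df.apply(lambda c: pd.to_numeric(c.map(lambda v: v.strip()), errors="coerce"))
    return df


def read_table(
    path,
    format: str = "tabular",
    collapse_duplicates: str | None = None,
) -> ExpressionMatrix:
    """Read a feature matrix from one of the supported text dialects.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"tabular", "pcl", "geo_series_matrix"}
        Input dialect.
    collapse_duplicates : {None, "mean"}
        If "mean", rows sharing an id are averaged (probe collapsing);
        otherwise duplicate ids are made unique by suffixing.

    Returns
    -------
    ExpressionMatrix
        Items in file order; missing values imputed with the row mean.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    text = path.read_text()

    if format == "geo_series_matrix":
        lines = text.splitlines()
        try:
            start = next(i for i, ln in enumerate(lines)
                         if ln.startswith("!series_matrix_table_begin"))
            end = next(i for i, ln in enumerate(lines)
                       if ln.startswith("!series_matrix_table_end"))
        except StopIteration:
            raise FormatError(
                f"{path}: missing !series_matrix_table_begin/end delimiters"
            ) from None
        text = "\n".join(lines[start + 1:end])

    df = _read_tsv_block(text, str(path))

    if format == "pcl":
        drop_cols = [c for c in df.columns if c.strip().lower() in _PCL_META_COLS]
        df = df.drop(columns=drop_cols)
        keep = [str(i).strip().lower() not in _PCL_META_ROWS for i in df.index]
        df = df.loc[keep]

    df = _impute_missing(df)
    df = _dedupe_or_collapse(df, collapse_duplicates)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise FormatError(f"{path}: non-numeric values in columns {bad}")
    return ExpressionMatrix.from_dataframe(df)


# ---------------------------------------------------------------------------
# output writers


def write_outputs(result, matrix: ExpressionMatrix, out_prefix) -> dict:
    """Write assignment, edge and heat-map tables for an ensemble result.

    Returns a dict mapping output kind to the written path:
    ``clusters`` (item_id, cluster, confidence), ``edges`` (source, target,
    affinity > 0, 6 decimals) and ``heatmap`` (rows reordered by cluster).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ids = matrix.item_ids
    labels = np.asarray(result.final_labels)
    conf = np.asarray(result.confidence)

    paths = {}
    cl_path = out_prefix.with_name(out_prefix.name + "_clusters.tsv")
    with open(cl_path, "w") as fh:
        fh.write("item_id\tcluster\tconfidence\n")
        for i, item in enumerate(ids):
            fh.write(f"{item}\t{labels[i]}\t{conf[i]:.4f}\n")
    paths["clusters"] = cl_path

    aff = np.asarray(result.affinity)
    edge_path = out_prefix.with_name(out_prefix.name + "_edges.tsv")
    with open(edge_path, "w") as fh:
        fh.write("source\ttarget\taffinity\n")
        n = len(ids)
        for a in range(n):
            for b in range(a + 1, n):
                if aff[a, b] > 0:
                    fh.write(f"{ids[a]}\t{ids[b]}\t{aff[a, b]:.6f}\n")
    paths["edges"] = edge_path

    order = np.lexsort((np.arange(len(ids)), labels))
    hm_path = out_prefix.with_name(out_prefix.name + "_heatmap.tsv")
    with open(hm_path, "w") as fh:
        fh.write("item_id\tcluster\t" + "\t".join(matrix.feature_ids) + "\n")
        for i in order:
            vals = "\t".join(f"{v:.6g}" for v in matrix.values[i])
            fh.write(f"{ids[i]}\t{labels[i]}\t{vals}\n")
    paths["heatmap"] = hm_path
    return paths


def read_assignments(path) -> pd.DataFrame:
    """Read back a cluster assignment table written by :func:`write_outputs`."""
    df = pd.read_csv(path, sep="\t", dtype={"item_id": str})
    expected = ["item_id", "cluster", "confidence"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df
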