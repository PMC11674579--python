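"""Delimited-text readers and writers for pipeline inputs and outputs.

Time series are stored regions-as-rows with a leading ``region`` label
column and one column per timepoint.  Square matrices (structural weights,
high-order matrices) use labeled rows and columns; centroids are a
``region, x, y, z`` table.  All formats round-trip losslessly to the
written precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .coupling import StructuralConnectome

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_matrix",
    "write_matrix",
    "read_connectome",
    "write_connectome",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed input file."""


def write_timeseries(data: np.ndarray, path, region_labels=None) -> None:
    """Write a (regions, timepoints) matrix as CSV with a region column."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-d (regions x timepoints)")
    if region_labels is None:
        region_labels = [f"R{i:03d}" for i in range(data.shape[0])]
    df = pd.DataFrame(data, index=pd.Index(region_labels, name="region"))
    df.columns = [f"t{j}" for j in range(data.shape[1])]
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_timeseries(path) -> tuple[np.ndarray, list[str]]:
    """Read a region-labeled CSV time-series matrix; returns (data, labels)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate region labels {dups}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
        raise ParseError(f"{path}: non-numeric cells in columns {list(bad)}")
    if not np.isfinite(arr).all():
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise ParseError(f"{path}: non-finite value at row {i + 2}, column {j + 2}")
    return arr.astype(float), [str(x) for x in df.index]


def write_matrix(matrix: np.ndarray, path, labels=None) -> None:
    """Write a square labeled matrix as CSV."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if labels is None:
        labels = [f"R{i:03d}" for i in range(matrix.shape[0])]
    df = pd.DataFrame(matrix, index=pd.Index(labels, name="region"), columns=labels)
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ParseError(f"{path}: matrix is not square ({df.shape})")
    return df.to_numpy(dtype=float), [str(x) for x in df.index]


def write_connectome(sc: StructuralConnectome, weights_path, coords_path) -> None:
    """Write a connectome as a weights matrix plus a centroid table."""
    write_matrix(sc.weights, weights_path, sc.region_labels)
    coords = pd.DataFrame(
        sc.coords,
        index=pd.Index(sc.region_labels, name="region"),
        columns=["x", "y", "z"],
    )
    coords.to_csv(coords_path, float_format=_FLOAT_FMT)


def read_connectome(weights_path, coords_path) -> StructuralConnectome:
    weights, labels = read_matrix(weights_path)
    coords_df = pd.read_csv(coords_path, index_col=0)
    if list(coords_df.index.astype(str)) != labels:
        raise ParseError("connectome weights and coordinates label mismatch")
    return StructuralConnectome(
        weights=weights, coords=coords_df.to_numpy(dtype=float), region_labels=labels
    )
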