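"""Export realized experiment slices.

Three text-friendly layouts:

* MTX — MatrixMarket coordinate format (1-based indices) plus two plain-text
  ID files (``<stem>.features.txt``, ``<stem>.samples.txt``).
* CSV — feature IDs as the first column, sample IDs as the header row;
  ``.`` decimal, no thousands separators.
* HDF5 — datasets ``/assay`` (2-D), ``/features``, ``/samples`` and one
  dataset per metadata column under ``/row_data`` and ``/col_data``.

Exports realize the assay, so they are meant for slices, not whole remote
matrices.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import SummarizedExperiment
from .errors import ValidationError

FORMATS = ("mtx", "csv", "h5")


def export_se(se: SummarizedExperiment, path, fmt: str,
              block_cells: int | None = None) -> list[str]:
    """Write a realized slice; returns the paths written."""
    if fmt not in FORMATS:
        raise ValidationError(f"unknown export format {fmt!r}; valid: {FORMATS}")
    kwargs = {} if block_cells is None else {"block_cells": block_cells}
    matrix = se.assay.realize(**kwargs)
    if fmt == "mtx":
        return _write_mtx(se, matrix, path)
    if fmt == "csv":
        return _write_csv(se, matrix, path)
    return _write_h5(se, matrix, path)


def _write_mtx(se, matrix, path) -> list[str]:
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    path = Path(path)
    mmwrite(str(path), coo_matrix(matrix))
    stem = path.with_suffix("") if path.suffix == ".mtx" else path
    feat_path = Path(f"{stem}.features.txt")
    samp_path = Path(f"{stem}.samples.txt")
    feat_path.write_text("\n".join(se.feature_ids) + "\n")
    samp_path.write_text("\n".join(se.sample_ids) + "\n")
    mtx_path = path if path.suffix == ".mtx" else Path(f"{path}.mtx")
    return [str(mtx_path), str(feat_path), str(samp_path)]


def _write_csv(se, matrix, path) -> list[str]:
    df = pd.DataFrame(matrix, index=pd.Index(se.feature_ids, name="feature_id"),
                      columns=se.sample_ids)
    df.to_csv(path)
    return [str(path)]


def _write_h5(se, matrix, path) -> list[str]:
    import h5py

    with h5py.File(path, "w") as f:
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("assay", data=np.asarray(matrix, dtype=np.float64))
        f.create_dataset("features", data=se.feature_ids, dtype=str_dt)
        f.create_dataset("samples", data=se.sample_ids, dtype=str_dt)
        rg = f.create_group("row_data")
        for col in se.row_data.columns:
            rg.create_dataset(col, data=_column(se.row_data[col], str_dt))
        cg = f.create_group("col_data")
        for col in se.col_data.columns:
            cg.create_dataset(col, data=_column(se.col_data[col], str_dt))
    return [str(path)]


def _column(series, str_dt):
    values = series.to_numpy()
    if values.dtype.kind in "OUS":
        return np.asarray([str(v) for v in values], dtype=str_dt)
    return values
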