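"""Deterministic synthetic expression fixtures.

Two scenarios emulate the shapes of data this package is meant to serve,
at desk scale and with no downloads:

``singlecell_panned``
    A single-cell-like count matrix.  Cells carry a ``selection`` label
    (four capture classes, as produced by antibody panning); each class has
    one designated marker gene whose mean is multiplied by the effect size
    in its own class.

``cohort_msi``
    A tumor-cohort-like matrix.  Samples carry a continuous ``msi_like``
    instability score; one designated gene's mean is multiplied by the
    effect size in samples at or above the conventional threshold of 4.

Counts are negative-binomial with lognormal gene-level means.  All draws
come from one seeded generator in a documented order, so a spec is a
stable, bit-reproducible fixture: same spec, same matrix, across runs and
back ends.  Writers emit the HDF5 layout the mock HDF-REST service serves
and the SQLite schema the SQL back end reads, plus a CSV bundle.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FeatureTable, SampleTable
from .errors import ValidationError
from .ranges import GenomicRanges
from .sql_backend import create_schema

#: Capture-class labels for the single-cell scenario (antibody panning
#: fractions plus the unpanned remainder).
PANNING_CLASSES = ("CD45pos", "GFAPpos", "Thy1pos", "unpanned")

#: Instability-score threshold above which the cohort scenario's designated
#: gene is upregulated; matches the conventional MSIsensor cutoff.
MSI_THRESHOLD = 4.0

_GENE_LENGTH = 1_000
_GENE_GAP = 100


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture.

    ``effect`` is the fold-change applied to marker/score-linked genes
    (> 1); ``nb_dispersion`` is the negative-binomial dispersion (variance
    = mu + dispersion * mu^2).  ``chunk_shape`` controls HDF5 output layout.
    """

    n_features: int = 500
    n_samples: int = 400
    seed: int = 0
    scenario: str = "singlecell_panned"
    effect: float = 4.0
    nb_dispersion: float = 0.5
    chunk_shape: tuple[int, int] = (64, 64)

    def __post_init__(self):
        if self.n_features < 1 or self.n_samples < 1:
            raise ValidationError("fixture dimensions must be positive")
        if self.effect <= 1.0:
            raise ValidationError(f"effect fold-change must be > 1, got {self.effect}")
        if self.scenario not in ("singlecell_panned", "cohort_msi"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")


@dataclass(frozen=True)
class FixtureData:
    """A simulated matrix with aligned metadata and truth bookkeeping."""

    matrix: np.ndarray  # (n_features, n_samples) float64 counts
    row_data: FeatureTable
    col_data: SampleTable
    row_ranges: GenomicRanges
    spec: FixtureSpec
    #: scenario truth: class label -> marker feature_id (singlecell_panned)
    #: or {"msi_gene": feature_id} (cohort_msi)
    markers: dict = field(default_factory=dict)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               dispersion: float) -> np.ndarray:
    """NB draws at mean ``mu``: gamma-Poisson mixture with shape 1/dispersion."""
    if dispersion <= 0:
        return rng.poisson(mu).astype(np.float64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam).astype(np.float64)


def _feature_ranges(n_features: int) -> GenomicRanges:
    """Non-overlapping consecutive intervals, first half on chr1, rest on chr2."""
    half = (n_features + 1) // 2
    seqs, starts, ends, strands = [], [], [], []
    for i in range(n_features):
        chrom = "chr1" if i < half else "chr2"
        k = i if i < half else i - half
        start = 1 + k * (_GENE_LENGTH + _GENE_GAP)
        seqs.append(chrom)
        starts.append(start)
        ends.append(start + _GENE_LENGTH - 1)
        strands.append("+" if i % 2 == 0 else "-")
    return GenomicRanges(tuple(seqs), tuple(starts), tuple(ends), tuple(strands))


def simulate_counts(spec: FixtureSpec) -> FixtureData:
    """Simulate one fixture; identical specs produce bit-identical output.

    Draw order (fixed for reproducibility): gene base means, sample
    covariate, count matrix row by row.
    """
    rng = np.random.default_rng(spec.seed)
    g, n = spec.n_features, spec.n_samples

    feature_ids = [f"g{i:04d}" for i in range(g)]
    symbols = [f"SYM{i:04d}" for i in range(g)]
    base_mu = rng.lognormal(mean=1.0, sigma=1.0, size=g)

    markers: dict = {}
    marker_class = np.array([""] * g, dtype=object)
    mu = np.tile(base_mu[:, None], (1, n))  # per-cell means, modified below

    if spec.scenario == "singlecell_panned":
        labels = np.array(PANNING_CLASSES)[rng.integers(0, len(PANNING_CLASSES), n)]
        col_columns = {"selection": labels}
        # one designated marker gene per class, spread across the matrix
        marker_rows = np.linspace(0, g - 1, len(PANNING_CLASSES)).astype(int)
        for cls, row in zip(PANNING_CLASSES, marker_rows):
            markers[cls] = feature_ids[row]
            marker_class[row] = cls
            mu[row, labels == cls] *= spec.effect
    else:  # cohort_msi
        n_high = n * 3 // 10  # fixed 70/30 low/high split keeps both strata populated
        low = rng.uniform(0.0, MSI_THRESHOLD, n - n_high)
        high = rng.uniform(MSI_THRESHOLD, 30.0, n_high)
        score = rng.permutation(np.concatenate([low, high]))
        col_columns = {"msi_like": score}
        row = g // 2
        markers["msi_gene"] = feature_ids[row]
        marker_class[row] = "msi"
        mu[row, score >= MSI_THRESHOLD] *= spec.effect

    matrix = np.empty((g, n), dtype=np.float64)
    for i in range(g):  # row-by-row keeps the draw order documented and stable
        matrix[i] = _nb_counts(rng, mu[i], spec.nb_dispersion)

    row_data = FeatureTable(feature_ids, {
        "symbol": symbols,
        "marker_class": marker_class.astype(str),
    })
    sample_ids = [f"s{j:04d}" for j in range(n)]
    col_data = SampleTable(sample_ids, col_columns)
    return FixtureData(matrix, row_data, col_data, _feature_ranges(g), spec, markers)


# ---------------------------------------------------------------------------
# Writers

def write_h5_fixture(data: FixtureData, path, chunk_shape=None):
    """Write the fixture as the HDF5 layout the mock service serves.

    Datasets: ``/assay`` (2-D float64, chunked), ``/features``, ``/samples``
    (UTF-8 strings) and one 1-D dataset per metadata column under
    ``/row_data`` and ``/col_data``.  Genomic coordinates land in
    ``/row_data/{seqname,start,end,strand}``.
    """
    import h5py

    chunks = tuple(chunk_shape or data.spec.chunk_shape)
    chunks = (min(chunks[0], data.matrix.shape[0]),
              min(chunks[1], data.matrix.shape[1]))
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("assay", data=data.matrix, chunks=chunks)
        f.create_dataset("features", data=data.row_data.ids, dtype=str_dt)
        f.create_dataset("samples", data=data.col_data.ids, dtype=str_dt)
        rg, cg = f.create_group("row_data"), f.create_group("col_data")
        for col in data.row_data.columns:
            rg.create_dataset(col, data=_h5_column(data.row_data[col], str_dt))
        r = data.row_ranges
        rg.create_dataset("seqname", data=list(r.seqnames), dtype=str_dt)
        rg.create_dataset("start", data=list(r.starts))
        rg.create_dataset("end", data=list(r.ends))
        rg.create_dataset("strand", data=list(r.strands), dtype=str_dt)
        for col in data.col_data.columns:
            cg.create_dataset(col, data=_h5_column(data.col_data[col], str_dt))
    return path


def _h5_column(series: pd.Series, str_dt):
    values = series.to_numpy()
    if values.dtype.kind in "OUS":
        return np.asarray([str(v) for v in values], dtype=str_dt)
    return values


def write_sql_fixture(data: FixtureData, path, cohort: str | None = None):
    """Write the fixture as a SQLite triple store (dense: every pair present).

    ``cohort`` optionally stamps a constant cohort column on the sample
    table, handy for predicate tests.
    """
    conn = sqlite3.connect(str(path))
    try:
        create_schema(conn)
        r = data.row_ranges
        feat = pd.DataFrame({
            "feature_id": data.row_data.ids,
            "seqname": list(r.seqnames),
            "start": list(r.starts),
            "end": list(r.ends),
            "strand": list(r.strands),
        })
        for col in data.row_data.columns:
            feat[col] = data.row_data[col].to_numpy()
        samp = pd.DataFrame({"sample_id": data.col_data.ids})
        for col in data.col_data.columns:
            samp[col] = data.col_data[col].to_numpy()
        if cohort is not None:
            samp["cohort"] = cohort
        g, n = data.matrix.shape
        long = pd.DataFrame({
            "feature_id": np.repeat(data.row_data.ids, n),
            "sample_id": np.tile(data.col_data.ids, g),
            "value": data.matrix.ravel(),
        })
        feat.to_sql("feature", conn, if_exists="replace", index=False)
        samp.to_sql("sample", conn, if_exists="replace", index=False)
        long.to_sql("assay", conn, if_exists="replace", index=False)
        conn.commit()
    finally:
        conn.close()
    return path


def write_csv_bundle(data: FixtureData, prefix):
    """Write features.csv / samples.csv / assay.csv (long format) at ``prefix``."""
    prefix = str(prefix)
    r = data.row_ranges
    feat = pd.DataFrame({"feature_id": data.row_data.ids,
                         "seqname": list(r.seqnames),
                         "start": list(r.starts), "end": list(r.ends),
                         "strand": list(r.strands)})
    for col in data.row_data.columns:
        feat[col] = data.row_data[col].to_numpy()
    samp = pd.DataFrame({"sample_id": data.col_data.ids})
    for col in data.col_data.columns:
        samp[col] = data.col_data[col].to_numpy()
    g, n = data.matrix.shape
    long = pd.DataFrame({
        "feature_id": np.repeat(data.row_data.ids, n),
        "sample_id": np.tile(data.col_data.ids, g),
        "value": data.matrix.ravel(),
    })
    paths = (f"{prefix}features.csv", f"{prefix}samples.csv", f"{prefix}assay.csv")
    feat.to_csv(paths[0], index=False)
    samp.to_csv(paths[1], index=False)
    long.to_csv(paths[2], index=False)
    return paths
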