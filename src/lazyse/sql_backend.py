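"""SummarizedExperiments from relational triple stores.

The schema is deliberately plain: a long-format assay table with one row
per (feature_id, sample_id, value) triple, plus a feature annotation table
and a sample covariate table.  Building an experiment reads only the two
annotation tables (sorted by ID for a deterministic axis order); the assay
is exposed as a lazy seed that turns each block read into one canonical
``SELECT`` with IN-lists, executed on demand and pivoted long-to-wide.

Generated SQL restricts itself to SELECT/WHERE/IN/ORDER BY so the same text
is valid on any portable engine.  IN-lists are sorted and single-quoted
with quote-doubling; identical selections therefore produce byte-identical
statements, which makes query logs diffable and tests deterministic.

Missing (feature, sample) pairs pivot to NaN by default — an absent record
is not evidence of zero expression — with an explicit ``fill`` constant
available for sparse count data.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FeatureTable, SampleTable, SummarizedExperiment, make_se
from .delayed import DelayedMatrix
from .errors import SchemaError, ValidationError
from .ranges import GenomicRanges

DDL = """\
CREATE TABLE IF NOT EXISTS feature (
    feature_id TEXT PRIMARY KEY,
    symbol     TEXT,
    seqname    TEXT,
    start      INTEGER,
    end        INTEGER,
    strand     TEXT
);
CREATE TABLE IF NOT EXISTS sample (
    sample_id  TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS assay (
    feature_id TEXT NOT NULL,
    sample_id  TEXT NOT NULL,
    value      REAL,
    PRIMARY KEY (feature_id, sample_id)
);
"""


@dataclass(frozen=True)
class SchemaNames:
    """Table/column names of the triple store; defaults fit the bundled DDL."""

    assay_table: str = "assay"
    feature_table: str = "feature"
    sample_table: str = "sample"
    feature_id: str = "feature_id"
    sample_id: str = "sample_id"
    value: str = "value"


def _quote(identifier: str) -> str:
    """Single-quote a literal, doubling embedded quotes."""
    return "'" + identifier.replace("'", "''") + "'"


def translate_selection_to_sql(features, samples,
                               schema: SchemaNames = SchemaNames()) -> str:
    """Canonical long-format SELECT for a feature × sample selection.

    IDs are sorted and escaped; identical selections yield byte-identical
    SQL regardless of input order.
    """
    features = sorted(set(str(f) for f in features))
    samples = sorted(set(str(s) for s in samples))
    if not features or not samples:
        raise ValidationError("selection must name at least one feature and one sample")
    f_list = ", ".join(_quote(f) for f in features)
    s_list = ", ".join(_quote(s) for s in samples)
    return (
        f"SELECT {schema.feature_id}, {schema.sample_id}, {schema.value} "
        f"FROM {schema.assay_table} "
        f"WHERE {schema.feature_id} IN ({f_list}) "
        f"AND {schema.sample_id} IN ({s_list}) "
        f"ORDER BY {schema.feature_id}, {schema.sample_id}"
    )


def pivot_long_to_dense(records, feature_order, sample_order,
                        fill=np.nan) -> np.ndarray:
    """Pivot (feature_id, sample_id, value) records to a dense matrix.

    ``matrix[i, j]`` is the value for ``(feature_order[i], sample_order[j])``
    when a record exists, else ``fill``.  Records outside the given orders,
    or duplicated pairs, are errors.
    """
    f_pos = {f: i for i, f in enumerate(feature_order)}
    s_pos = {s: j for j, s in enumerate(sample_order)}
    out = np.full((len(f_pos), len(s_pos)), fill, dtype=np.float64)
    seen = np.zeros(out.shape, dtype=bool)
    for fid, sid, value in records:
        i = f_pos.get(fid)
        j = s_pos.get(sid)
        if i is None:
            raise SchemaError(f"record names unknown feature {fid!r}")
        if j is None:
            raise SchemaError(f"record names unknown sample {sid!r}")
        if seen[i, j]:
            raise SchemaError(f"duplicate assay record for ({fid!r}, {sid!r})")
        seen[i, j] = True
        out[i, j] = value
    return out


class SQLSeed:
    """Lazy seed over a long-format assay table.

    Each block read issues one canonical SELECT for the block's feature and
    sample IDs and pivots the result.  Executed statements are appended to
    ``statement_log`` so tests can audit query economy.
    """

    def __init__(self, connection: sqlite3.Connection, feature_ids, sample_ids,
                 schema: SchemaNames = SchemaNames(), fill=np.nan):
        self._conn = connection
        self._feature_ids = list(feature_ids)
        self._sample_ids = list(sample_ids)
        self._schema = schema
        self._fill = fill
        self.shape = (len(self._feature_ids), len(self._sample_ids))
        self.value_kind = "float64"
        self.chunk_shape = None
        self.statement_log: list[str] = []

    def read_block(self, row_interval, col_interval) -> np.ndarray:
        r0, r1 = row_interval
        c0, c1 = col_interval
        if not (0 <= r0 <= r1 <= self.shape[0] and 0 <= c0 <= c1 <= self.shape[1]):
            raise ValidationError(
                f"block [{r0}:{r1}, {c0}:{c1}] outside shape {self.shape}"
            )
        return self._fetch(self._feature_ids[r0:r1], self._sample_ids[c0:c1])

    def read_selection(self, rows, cols) -> np.ndarray:
        """Scattered read: one statement for the exact ID sets (no overfetch)."""
        feats = [self._feature_ids[i] for i in rows]
        samps = [self._sample_ids[j] for j in cols]
        return self._fetch(feats, samps)

    def _fetch(self, features, samples) -> np.ndarray:
        if not features or not samples:
            return np.empty((len(features), len(samples)), dtype=np.float64)
        sql = translate_selection_to_sql(features, samples, self._schema)
        self.statement_log.append(sql)
        records = self._conn.execute(sql).fetchall()
        return pivot_long_to_dense(records, features, samples, fill=self._fill)


_PREDICATE_OPS = {"=", "==", "!=", "<", "<=", ">", ">="}

_MANDATORY = ("feature_id", "sample_id", "value")


def _table_columns(conn, table: str) -> list[str]:
    try:
        cur = conn.execute(f"SELECT * FROM {table} LIMIT 0")
    except sqlite3.Error as exc:
        raise SchemaError(f"cannot read table {table!r}: {exc}")
    return [d[0] for d in cur.description]


def build_se_from_sql(connection: sqlite3.Connection,
                      sample_predicate: tuple[str, str, object] | None = None,
                      schema: SchemaNames = SchemaNames(),
                      fill=np.nan) -> SummarizedExperiment:
    """Derive a SummarizedExperiment from a triple store.

    Feature and sample annotation tables are read eagerly and sorted by ID;
    the assay stays lazy (zero assay-table rows are scanned at build time).
    ``sample_predicate`` is a ``(column, comparator, constant)`` triple
    restricting the sample axis, e.g. ``("cohort", "=", "COAD")``.
    Row ranges are attached when the feature table carries
    seqname/start/end columns.
    """
    assay_cols = _table_columns(connection, schema.assay_table)
    missing = [c for c in (schema.feature_id, schema.sample_id, schema.value)
               if c not in assay_cols]
    if missing:
        raise SchemaError(
            f"assay table {schema.assay_table!r} lacks column(s) {missing}"
        )

    feat_df = pd.read_sql_query(
        f"SELECT * FROM {schema.feature_table} ORDER BY {schema.feature_id}",
        connection,
    )
    if schema.feature_id not in feat_df.columns:
        raise SchemaError(
            f"feature table lacks key column {schema.feature_id!r}"
        )

    sample_sql = f"SELECT * FROM {schema.sample_table}"
    if sample_predicate is not None:
        column, op, constant = sample_predicate
        if op not in _PREDICATE_OPS:
            raise SchemaError(f"unsupported predicate comparator {op!r}")
        if column not in _table_columns(connection, schema.sample_table):
            raise SchemaError(f"predicate column {column!r} not in sample table")
        literal = _quote(constant) if isinstance(constant, str) else repr(constant)
        sample_sql += f" WHERE {column} {'=' if op == '==' else op} {literal}"
    sample_sql += f" ORDER BY {schema.sample_id}"
    samp_df = pd.read_sql_query(sample_sql, connection)
    if schema.sample_id not in samp_df.columns:
        raise SchemaError(f"sample table lacks key column {schema.sample_id!r}")

    feature_ids = feat_df[schema.feature_id].astype(str).tolist()
    sample_ids = samp_df[schema.sample_id].astype(str).tolist()
    row_data = FeatureTable(feature_ids,
                            feat_df.drop(columns=[schema.feature_id]))
    col_data = SampleTable(sample_ids,
                           samp_df.drop(columns=[schema.sample_id]))

    ranges = None
    coord_cols = {"seqname", "start", "end"}
    if coord_cols.issubset(feat_df.columns) and len(feat_df) and \
            feat_df[list(coord_cols)].notna().all().all():
        strands = (feat_df["strand"].astype(str).tolist()
                   if "strand" in feat_df.columns
                   else ["*"] * len(feat_df))
        ranges = GenomicRanges(
            tuple(feat_df["seqname"].astype(str)),
            tuple(int(v) for v in feat_df["start"]),
            tuple(int(v) for v in feat_df["end"]),
            tuple(strands),
        )

    seed = SQLSeed(connection, feature_ids, sample_ids, schema, fill=fill)
    return make_se(DelayedMatrix.from_seed(seed), row_data, col_data, ranges)


def create_schema(connection: sqlite3.Connection):
    """Apply the bundled DDL (idempotent)."""
    connection.executescript(DDL)
    connection.commit()


def load_csv_tables(connection: sqlite3.Connection, feature_csv, sample_csv,
                    assay_csv):
    """Ingest a CSV bundle (feature/sample/assay tables) into the schema.

    The assay CSV must be long-format with feature_id, sample_id, value
    columns.  Tables are replaced, not appended.
    """
    feat = pd.read_csv(feature_csv)
    samp = pd.read_csv(sample_csv)
    assay = pd.read_csv(assay_csv)
    missing = [c for c in _MANDATORY if c not in assay.columns]
    if missing:
        raise SchemaError(f"assay CSV lacks column(s) {missing}")
    feat.to_sql("feature", connection, if_exists="replace", index=False)
    samp.to_sql("sample", connection, if_exists="replace", index=False)
    assay.to_sql("assay", connection, if_exists="replace", index=False)
    connection.commit()
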