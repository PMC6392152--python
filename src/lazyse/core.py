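"""SummarizedExperiment-style container with lazy assays.

The container binds a G × N assay matrix (a :class:`~lazyse.delayed.DelayedMatrix`)
to a feature table (rowData, G rows), a sample table (colData, N rows) and
optionally per-feature genomic ranges.  Subsetting with ``se[K, S]`` filters
and reorders all of them in lockstep while the assay stays a delayed view —
no values move until realization.

Selectors on either axis may be identifier lists, 0-based position lists,
boolean masks, or ``None`` (keep all).  Feature and sample identifiers must
be unique, so identifier selection is unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .delayed import DelayedMatrix, InMemorySeed
from .errors import SelectorError, ValidationError
from .ranges import GenomicRanges, overlaps_any

logger = logging.getLogger(__name__)


class _IDTable:
    """Ordered metadata table keyed by unique, non-empty string identifiers."""

    _axis = "feature"

    def __init__(self, ids: Sequence[str], columns: Mapping[str, Sequence] | pd.DataFrame | None = None):
        ids = [str(i) for i in ids]
        if any(i == "" for i in ids):
            raise ValidationError(f"{self._axis} IDs must be non-empty strings")
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dups = sorted({i for i in ids if i in seen or seen.add(i)})
            raise ValidationError(f"duplicate {self._axis} IDs: {dups[:5]}")
        if columns is None:
            df = pd.DataFrame(index=pd.Index(ids, name=f"{self._axis}_id"))
        else:
            df = pd.DataFrame(dict(columns) if not isinstance(columns, pd.DataFrame)
                              else columns)
            if len(df) != len(ids):
                raise ValidationError(
                    f"{self._axis} metadata columns have {len(df)} rows "
                    f"for {len(ids)} IDs"
                )
            df.index = pd.Index(ids, name=f"{self._axis}_id")
        self._df = df

    @property
    def ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def columns(self) -> list[str]:
        return list(self._df.columns)

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying DataFrame (IDs on the index); treat as read-only."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __getitem__(self, column: str) -> pd.Series:
        if column not in self._df.columns:
            raise SelectorError(
                f"no {self._axis} metadata column {column!r}; "
                f"available: {self.columns}"
            )
        return self._df[column]

    def resolve_ids(self, identifiers: Sequence[str]) -> np.ndarray:
        lookup = {i: p for p, i in enumerate(self._df.index)}
        missing = [i for i in identifiers if i not in lookup]
        if missing:
            raise SelectorError(
                f"unknown {self._axis} ID(s): {missing}"
            )
        return np.asarray([lookup[i] for i in identifiers], dtype=np.int64)

    def take(self, positions) -> "_IDTable":
        out = object.__new__(type(self))
        out._df = self._df.iloc[np.asarray(positions, dtype=np.int64)]
        return out


class FeatureTable(_IDTable):
    """rowData: per-feature annotations keyed by feature ID."""

    _axis = "feature"


class SampleTable(_IDTable):
    """colData: per-sample covariates keyed by sample ID."""

    _axis = "sample"


def _resolve_selector(selector, table: _IDTable, axis: str) -> np.ndarray | None:
    """Turn a selector into 0-based positions; ``None`` means keep-all."""
    if selector is None or (isinstance(selector, str) and selector == "all"):
        return None
    if isinstance(selector, slice):
        if selector == slice(None):
            return None
        raise SelectorError(f"only the all-slice is supported on the {axis} axis")
    arr = np.asarray(selector)
    if arr.dtype == bool:
        if arr.size != len(table):
            raise SelectorError(
                f"{axis} mask length {arr.size} != dimension {len(table)}"
            )
        return np.nonzero(arr)[0]
    if arr.size == 0:
        return np.asarray([], dtype=np.int64)
    if arr.dtype.kind in "iu":
        pos = arr.astype(np.int64).reshape(-1)
        bad = pos[(pos < 0) | (pos >= len(table))]
        if bad.size:
            raise SelectorError(
                f"{axis} position {bad[0]} out of range [0, {len(table)})"
            )
        return pos
    if arr.dtype.kind in "UOS":
        return table.resolve_ids([str(x) for x in arr.reshape(-1)])
    raise SelectorError(f"cannot interpret {axis} selector of dtype {arr.dtype}")


@dataclass(frozen=True)
class SummarizedExperiment:
    """Assay matrix bound to feature/sample metadata and optional ranges."""

    assay: DelayedMatrix
    row_data: FeatureTable
    col_data: SampleTable
    row_ranges: GenomicRanges | None = None

    def __post_init__(self):
        g, n = self.assay.shape
        if g != len(self.row_data):
            raise ValidationError(
                f"feature axis mismatch: assay has {g} rows, "
                f"row_data has {len(self.row_data)}"
            )
        if n != len(self.col_data):
            raise ValidationError(
                f"sample axis mismatch: assay has {n} columns, "
                f"col_data has {len(self.col_data)}"
            )
        if self.row_ranges is not None and len(self.row_ranges) != g:
            raise ValidationError(
                f"row_ranges has {len(self.row_ranges)} entries for {g} features"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.assay.shape

    @property
    def feature_ids(self) -> list[str]:
        return self.row_data.ids

    @property
    def sample_ids(self) -> list[str]:
        return self.col_data.ids

    def __getitem__(self, key) -> "SummarizedExperiment":
        if not isinstance(key, tuple) or len(key) != 2:
            raise SelectorError("use se[K, S] with selectors for both axes")
        return subset_se(self, key[0], key[1])

    def realize(self, **kwargs) -> np.ndarray:
        return self.assay.realize(**kwargs)


def make_se(assay, row_data: FeatureTable, col_data: SampleTable,
            row_ranges: GenomicRanges | None = None) -> SummarizedExperiment:
    """Construct a container; reads no assay values.

    ``assay`` may be a DelayedMatrix or a plain 2-D array (wrapped in an
    in-memory seed).
    """
    if not isinstance(assay, DelayedMatrix):
        assay = DelayedMatrix.from_seed(
            assay if hasattr(assay, "read_block") else InMemorySeed(np.asarray(assay))
        )
    return SummarizedExperiment(assay, row_data, col_data, row_ranges)


def subset_se(se: SummarizedExperiment, features=None, samples=None
              ) -> SummarizedExperiment:
    """The ``X[K, S]`` idiom: filter/reorder metadata and delay the assay.

    Selection order is preserved and duplicated positions are repeated; no
    assay data is fetched.
    """
    k = _resolve_selector(features, se.row_data, "feature")
    s = _resolve_selector(samples, se.col_data, "sample")
    assay = se.assay.subset(k, s)
    row_data = se.row_data if k is None else se.row_data.take(k)
    col_data = se.col_data if s is None else se.col_data.take(s)
    ranges = se.row_ranges
    if ranges is not None and k is not None:
        ranges = ranges.take(k)
    return SummarizedExperiment(assay, row_data, col_data, ranges)


def subset_by_overlaps(se: SummarizedExperiment, roi: GenomicRanges,
                       strand_aware: bool = False) -> SummarizedExperiment:
    """Keep features whose range overlaps any ROI interval, in original order."""
    if se.row_ranges is None:
        raise ValidationError(
            "subset_by_overlaps requires row_ranges on the experiment"
        )
    mask = overlaps_any(se.row_ranges, roi, strand_aware=strand_aware)
    return subset_se(se, mask, None)


def bind_sample_data(se: SummarizedExperiment, table, key_column: str,
                     value_columns: Sequence[str]) -> SummarizedExperiment:
    """Join external sample covariates onto colData by sample ID.

    ``table`` is a DataFrame or record mapping with unique keys in
    ``key_column``.  Samples absent from the table receive NaN (the missing
    marker); stratification operations drop those samples and report the
    count.  Existing colData columns are never silently overwritten.
    """
    df = pd.DataFrame(table)
    for col in (key_column, *value_columns):
        if col not in df.columns:
            raise ValidationError(f"bind table has no column {col!r}")
    if df[key_column].duplicated().any():
        dups = df.loc[df[key_column].duplicated(), key_column].tolist()
        raise ValidationError(f"duplicate keys in bind table: {dups[:5]}")
    collisions = [c for c in value_columns if c in se.col_data.columns]
    if collisions:
        raise ValidationError(
            f"column(s) {collisions} already present in col_data; "
            "refusing to overwrite"
        )
    keyed = df.set_index(df[key_column].astype(str))[list(value_columns)]
    joined = se.col_data.frame.join(keyed, how="left")
    new_col_data = SampleTable(se.col_data.ids, joined)
    return SummarizedExperiment(se.assay, se.row_data, new_col_data, se.row_ranges)


_COMPLEMENT = {">=": "<", ">": "<=", "<": ">=", "<=": ">", "==": "!=", "!=": "=="}

_COMPARATORS = {
    ">=": np.greater_equal, ">": np.greater,
    "<": np.less, "<=": np.less_equal,
    "==": np.equal, "!=": np.not_equal,
}


@dataclass(frozen=True)
class GeneGroupResult:
    """Per-group transformed expression values for one feature."""

    feature_id: str
    groups: dict[str, np.ndarray]
    n_dropped: int = 0

    def summary(self) -> pd.DataFrame:
        """Per-group n, mean, median of the transformed values."""
        rows = [
            {"group": g, "n": v.size,
             "mean": float(np.mean(v)) if v.size else float("nan"),
             "median": float(np.median(v)) if v.size else float("nan")}
            for g, v in self.groups.items()
        ]
        return pd.DataFrame(rows, columns=["group", "n", "mean", "median"])


def resolve_feature(se: SummarizedExperiment, feature) -> int:
    """Resolve a feature to its row position.

    ``feature`` is either an identifier string or a ``(column, value)`` pair
    matched against a rowData column; the pair form takes the FIRST match
    (the match-on-symbol idiom) and warns when the match is ambiguous.
    """
    if isinstance(feature, tuple):
        column, value = feature
        hits = np.nonzero((se.row_data[column] == value).to_numpy())[0]
        if hits.size == 0:
            raise SelectorError(
                f"no feature with {column!r} == {value!r}"
            )
        if hits.size > 1:
            logger.warning(
                "%d features match %s == %r; using the first (row %d)",
                hits.size, column, value, hits[0],
            )
        return int(hits[0])
    return int(se.row_data.resolve_ids([str(feature)])[0])


def gene_by_group(se: SummarizedExperiment, feature, group_col: str,
                  comparator: str | None = None, threshold: float | None = None,
                  transform: str = "identity") -> GeneGroupResult:
    """Split one feature's expression across sample groups.

    Exactly one assay row is fetched.  With a comparator and threshold the
    samples split into two groups labelled by the predicate and its
    complement (e.g. ``"<4"`` / ``">=4"`` for ``>= 4``); without one, the
    distinct values of ``group_col`` define the groups.  Samples whose
    grouping value is missing are excluded and counted in ``n_dropped``.
    """
    from .delayed import TRANSFORMS

    if transform not in TRANSFORMS:
        raise SelectorError(
            f"unknown transform {transform!r}; valid: {sorted(TRANSFORMS)}"
        )
    row = resolve_feature(se, feature)
    covariate = se.col_data[group_col]
    values = se.assay.subset([row], None).realize()[0]
    values = TRANSFORMS[transform](values)

    present = covariate.notna().to_numpy()
    n_dropped = int((~present).sum())
    if n_dropped:
        logger.info("gene_by_group: dropped %d samples with missing %r",
                    n_dropped, group_col)
    values = values[present]
    covariate = covariate[present]

    feature_id = se.feature_ids[row]
    if comparator is not None:
        if threshold is None:
            raise SelectorError("a comparator requires a threshold")
        if comparator not in _COMPARATORS:
            raise SelectorError(
                f"unknown comparator {comparator!r}; valid: {sorted(_COMPARATORS)}"
            )
        t = threshold
        label = f"{comparator}{t:g}"
        other = f"{_COMPLEMENT[comparator]}{t:g}"
        in_group = _COMPARATORS[comparator](covariate.to_numpy(dtype=float), t)
        groups = {other: values[~in_group], label: values[in_group]}
    else:
        groups = {
            str(level): values[(covariate == level).to_numpy()]
            for level in sorted(covariate.unique(), key=str)
        }
    return GeneGroupResult(feature_id, groups, n_dropped)
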