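"""Lazy delayed matrices over block-readable seeds.

A :class:`DelayedMatrix` is a view: an ordered row map and column map into a
storage *seed* plus a chain of pending elementwise transforms.  Subsetting
and transform application compose maps and append to the chain without
touching storage; values move only when :meth:`DelayedMatrix.realize` or
:meth:`DelayedMatrix.block_iter` runs, and then in dense blocks bounded by a
cell budget so a full matrix never has to fit in memory.

Seeds implement a small contract: ``shape``, ``value_kind``, an optional
``chunk_shape``, and a pure ``read_block(row_interval, col_interval)``
returning the dense rectangle.  A seed may additionally provide
``read_selection(rows, cols)`` for scattered index sets (the remote seed
routes this through a request planner); without it, realization issues one
``read_block`` per maximal contiguous run pair, so no cell outside the
mapped rows × mapped columns is ever requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import SelectorError, ValidationError

#: Default realization budget: 2**20 values, a round 8 MiB of float64.
DEFAULT_BLOCK_CELLS = 1_048_576

#: Registered elementwise transforms.  A whitelist (rather than arbitrary
#: callables) keeps realization deterministic and leaves the door open to
#: server-side pushdown.
TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "log2p1": lambda x: np.log2(x + 1.0),
    "log10p1": lambda x: np.log10(x + 1.0),
}


@runtime_checkable
class Seed(Protocol):
    """Contract for block-readable 2-D storage."""

    shape: tuple[int, int]
    value_kind: str  # "float64" | "int64"
    chunk_shape: tuple[int, int] | None

    def read_block(self, row_interval: tuple[int, int],
                   col_interval: tuple[int, int]) -> np.ndarray:
        """Dense rectangle for half-open 0-based intervals."""
        ...


class InMemorySeed:
    """Seed over an in-memory 2-D array; the eager reference back end."""

    def __init__(self, array: np.ndarray, chunk_shape: tuple[int, int] | None = None):
        arr = np.asarray(array)
        if arr.ndim != 2:
            raise ValidationError(f"seed array must be 2-D, got ndim={arr.ndim}")
        self._array = arr
        self.shape = arr.shape
        self.value_kind = "int64" if np.issubdtype(arr.dtype, np.integer) else "float64"
        self.chunk_shape = chunk_shape

    def read_block(self, row_interval, col_interval):
        r0, r1 = row_interval
        c0, c1 = col_interval
        _check_interval(r0, r1, self.shape[0], "row")
        _check_interval(c0, c1, self.shape[1], "col")
        return np.asarray(self._array[r0:r1, c0:c1], dtype=np.float64)


class HDF5FileSeed:
    """Seed reading a named 2-D dataset from a local HDF5 file.

    The file handle is opened lazily on first read and kept open; chunk
    geometry is taken from the dataset's storage layout.
    """

    def __init__(self, path, dataset: str = "assay"):
        import h5py

        self._path = str(path)
        self._dataset = dataset
        self._h5py = h5py
        self._file = None
        with h5py.File(self._path, "r") as f:
            dset = f[dataset]
            if dset.ndim != 2:
                raise ValidationError(
                    f"dataset {dataset!r} in {path} is {dset.ndim}-D, need 2-D"
                )
            self.shape = tuple(dset.shape)
            self.chunk_shape = tuple(dset.chunks) if dset.chunks else None
            self.value_kind = (
                "int64" if np.issubdtype(dset.dtype, np.integer) else "float64"
            )

    def _dset(self):
        if self._file is None:
            self._file = self._h5py.File(self._path, "r")
        return self._file[self._dataset]

    def read_block(self, row_interval, col_interval):
        r0, r1 = row_interval
        c0, c1 = col_interval
        _check_interval(r0, r1, self.shape[0], "row")
        _check_interval(c0, c1, self.shape[1], "col")
        return np.asarray(self._dset()[r0:r1, c0:c1], dtype=np.float64)


def _check_interval(lo, hi, extent, axis):
    if not (0 <= lo <= hi <= extent):
        raise SelectorError(
            f"{axis} interval [{lo}, {hi}) outside [0, {extent})"
        )


def _as_index_array(indices, extent: int, axis: str) -> np.ndarray:
    idx = np.asarray(indices, dtype=np.int64).reshape(-1)
    if idx.size and (idx.min() < 0 or idx.max() >= extent):
        bad = idx[(idx < 0) | (idx >= extent)][0]
        raise SelectorError(f"{axis} index {bad} out of range [0, {extent})")
    return idx


def _runs(sorted_unique: np.ndarray) -> list[tuple[int, int]]:
    """Maximal consecutive runs of a sorted unique index vector, half-open."""
    if sorted_unique.size == 0:
        return []
    breaks = np.nonzero(np.diff(sorted_unique) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [sorted_unique.size - 1]))
    return [(int(sorted_unique[s]), int(sorted_unique[e]) + 1)
            for s, e in zip(starts, ends)]


@dataclass(frozen=True)
class DelayedMatrix:
    """A pending-operation view over a seed.

    ``row_map``/``col_map`` are 0-based seed indices in view order (repeats
    allowed); ``transforms`` are applied elementwise, in order, after fetch.
    """

    seed: Seed
    row_map: np.ndarray
    col_map: np.ndarray
    transforms: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "row_map",
                           _as_index_array(self.row_map, self.seed.shape[0], "row"))
        object.__setattr__(self, "col_map",
                           _as_index_array(self.col_map, self.seed.shape[1], "col"))
        unknown = [t for t in self.transforms if t not in TRANSFORMS]
        if unknown:
            raise SelectorError(
                f"unknown transform(s) {unknown}; valid: {sorted(TRANSFORMS)}"
            )

    @classmethod
    def from_seed(cls, seed: Seed) -> "DelayedMatrix":
        return cls(seed, np.arange(seed.shape[0]), np.arange(seed.shape[1]))

    @classmethod
    def from_array(cls, array: np.ndarray) -> "DelayedMatrix":
        return cls.from_seed(InMemorySeed(array))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_map.size, self.col_map.size)

    # -- delayed operations -------------------------------------------------

    def subset(self, rows: Sequence[int] | None = None,
               cols: Sequence[int] | None = None) -> "DelayedMatrix":
        """Compose a subset into the view; no seed reads.

        ``rows``/``cols`` index the *view* (0-based, repeats allowed);
        ``None`` keeps an axis whole.
        """
        row_map = self.row_map
        col_map = self.col_map
        if rows is not None:
            idx = _as_index_array(rows, row_map.size, "row")
            row_map = row_map[idx]
        if cols is not None:
            idx = _as_index_array(cols, col_map.size, "col")
            col_map = col_map[idx]
        return DelayedMatrix(self.seed, row_map, col_map, self.transforms)

    def apply(self, transform: str) -> "DelayedMatrix":
        """Append a registered elementwise transform to the pending chain."""
        if transform not in TRANSFORMS:
            raise SelectorError(
                f"unknown transform {transform!r}; valid: {sorted(TRANSFORMS)}"
            )
        return DelayedMatrix(self.seed, self.row_map, self.col_map,
                             self.transforms + (transform,))

    # -- realization --------------------------------------------------------

    def realize(self, block_cells: int = DEFAULT_BLOCK_CELLS) -> np.ndarray:
        """Materialize the view as a dense float64 matrix.

        Seed reads are partitioned into blocks of at most ``block_cells``
        values where geometry allows; duplicated map entries are filled by
        replication from a single fetch of the unique indices.
        """
        out = np.empty(self.shape, dtype=np.float64)
        for (r0, r1), (c0, c1), block in self.block_iter(block_cells):
            out[r0:r1, c0:c1] = block
        return out

    def block_iter(self, block_cells: int = DEFAULT_BLOCK_CELLS
                   ) -> Iterator[tuple[tuple[int, int], tuple[int, int], np.ndarray]]:
        """Tile the view into bounded dense blocks.

        Yields ``(row_interval, col_interval, block)`` triples whose
        intervals tile the view's index space exactly once, row-major;
        concatenation reproduces :meth:`realize`.
        """
        if block_cells < 1:
            raise ValidationError(f"block_cells must be >= 1, got {block_cells}")
        n_rows, n_cols = self.shape
        if n_rows == 0 or n_cols == 0:
            return
        # Full-width row bands when a row fits in budget, else column chunks.
        band = max(1, block_cells // n_cols) if n_cols <= block_cells else 1
        col_step = n_cols if n_cols <= block_cells else block_cells
        for r0 in range(0, n_rows, band):
            r1 = min(r0 + band, n_rows)
            for c0 in range(0, n_cols, col_step):
                c1 = min(c0 + col_step, n_cols)
                block = self._fetch_view_block(r0, r1, c0, c1)
                yield (r0, r1), (c0, c1), block

    def _fetch_view_block(self, r0, r1, c0, c1) -> np.ndarray:
        rows = self.row_map[r0:r1]
        cols = self.col_map[c0:c1]
        uniq_rows, row_inv = np.unique(rows, return_inverse=True)
        uniq_cols, col_inv = np.unique(cols, return_inverse=True)
        dense = self._fetch_unique(uniq_rows, uniq_cols)
        block = dense[np.ix_(row_inv, col_inv)]
        for name in self.transforms:
            block = TRANSFORMS[name](block)
        return block

    def _fetch_unique(self, uniq_rows: np.ndarray, uniq_cols: np.ndarray) -> np.ndarray:
        reader = getattr(self.seed, "read_selection", None)
        if reader is not None:
            return np.asarray(reader(uniq_rows.tolist(), uniq_cols.tolist()),
                              dtype=np.float64)
        dense = np.empty((uniq_rows.size, uniq_cols.size), dtype=np.float64)
        row_runs = _runs(uniq_rows)
        col_runs = _runs(uniq_cols)
        ro = 0
        for rr in row_runs:
            co = 0
            rn = rr[1] - rr[0]
            for cr in col_runs:
                cn = cr[1] - cr[0]
                dense[ro:ro + rn, co:co + cn] = self.seed.read_block(rr, cr)
                co += cn
            ro += rn
        return dense
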