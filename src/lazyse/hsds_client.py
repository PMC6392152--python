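"""Client for a minimal HDF-REST dialect, with a chunk-aware read planner.

The dialect (all GET, JSON bodies, 0-based half-open hyperslab bounds):

* ``{base}/about`` → ``{"api_version": "minimal-1"}``
* ``{base}/datasets?domain=D`` → ``{"datasets": [uuid, ...]}``
* ``{base}/datasets/{uuid}?domain=D`` →
  ``{"shape": {"dims": [g, n]}, "type": {"class": ...}, "layout": {"dims": [cr, cc]}}``
* ``{base}/datasets/{uuid}/value?domain=D&select=[r0:r1,c0:c1]`` →
  ``{"value": row-major nested lists}``

A :class:`RemoteDatasetHandle` satisfies the seed contract of
:mod:`lazyse.delayed`, so a remote dataset can back a delayed assay
directly.  Scattered selections are planned before any request is issued:
per axis, consecutive indices coalesce into runs, adjacent runs merge
greedily while the wasted fraction of the merged span stays within
``waste_ratio``, and the resulting rectangles are split (snapping to chunk
boundaries when possible) until each fits the per-request cell budget.
Transient failures (transport errors and 5xx) are retried with exponential
backoff; an oversized-selection 413 makes the client split the slab and try
again.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from .errors import ProtocolError, SelectorError, TransportError, ValidationError

DEFAULT_MAX_REQUEST_CELLS = 1_048_576
DEFAULT_WASTE_RATIO = 0.5


# ---------------------------------------------------------------------------
# Request planning

@dataclass(frozen=True)
class RequestPlan:
    """A deterministic set of rectangular reads covering a scattered selection.

    ``slabs`` are half-open 0-based rectangles ``((r0, r1), (c0, c1))``;
    ``gather`` maps each requested cell (position in the sorted-unique
    ``rows`` × ``cols`` grid) to the slab that covers it.  Local offsets
    within a slab are the seed index minus the slab origin.
    """

    rows: np.ndarray
    cols: np.ndarray
    slabs: list[tuple[tuple[int, int], tuple[int, int]]]
    gather: np.ndarray  # (len(rows), len(cols)) slab index per requested cell

    def gather_offsets(self, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Output rows/cols covered by slab ``k`` and their local offsets."""
        (r0, r1), (c0, c1) = self.slabs[k]
        out_r = np.nonzero((self.rows >= r0) & (self.rows < r1))[0]
        out_c = np.nonzero((self.cols >= c0) & (self.cols < c1))[0]
        return out_r, out_c, self.rows[out_r] - r0, self.cols[out_c] - c0


def _coalesce_runs(indices: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop, needed) maximal consecutive runs of sorted unique indices."""
    runs = []
    if indices.size:
        breaks = np.nonzero(np.diff(indices) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [indices.size - 1]))
        for s, e in zip(starts, ends):
            runs.append((int(indices[s]), int(indices[e]) + 1, int(e - s + 1)))
    return runs


def _merge_runs(runs: list[tuple[int, int, int]], waste_ratio: float
                ) -> list[tuple[int, int]]:
    """Greedy left-to-right merge while waste (unneeded/span) stays in bound."""
    merged: list[tuple[int, int]] = []
    cur_start, cur_stop, cur_needed = None, None, 0
    for start, stop, needed in runs:
        if cur_start is None:
            cur_start, cur_stop, cur_needed = start, stop, needed
            continue
        span = stop - cur_start
        total_needed = cur_needed + needed
        if span > 0 and (span - total_needed) / span <= waste_ratio:
            cur_stop, cur_needed = stop, total_needed
        else:
            merged.append((cur_start, cur_stop))
            cur_start, cur_stop, cur_needed = start, stop, needed
    if cur_start is not None:
        merged.append((cur_start, cur_stop))
    return merged


def _split_points(lo: int, hi: int, pieces: int, chunk: int | None) -> list[int]:
    """Cut [lo, hi) into ``pieces`` parts, snapping cuts to chunk boundaries."""
    raw = [lo + round((hi - lo) * k / pieces) for k in range(1, pieces)]
    if chunk:
        snapped = []
        prev = lo
        for cut in raw:
            aligned = round(cut / chunk) * chunk
            if prev < aligned < hi:
                cut = aligned
            if cut <= prev:
                cut = prev + 1
            snapped.append(min(cut, hi - 1))
            prev = snapped[-1]
        raw = sorted(set(snapped))
    return [lo] + raw + [hi]


def _split_slab(slab: tuple[tuple[int, int], tuple[int, int]],
                max_cells: int, chunk_shape) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    (r0, r1), (c0, c1) = slab
    cells = (r1 - r0) * (c1 - c0)
    if cells <= max_cells:
        return [slab]
    # split along the longer axis
    if (r1 - r0) >= (c1 - c0):
        pieces = -(-cells // max_cells)
        pieces = min(pieces, r1 - r0)
        chunk = chunk_shape[0] if chunk_shape else None
        cuts = _split_points(r0, r1, pieces, chunk)
        parts = [((a, b), (c0, c1)) for a, b in zip(cuts, cuts[1:])]
    else:
        pieces = -(-cells // max_cells)
        pieces = min(pieces, c1 - c0)
        chunk = chunk_shape[1] if chunk_shape else None
        cuts = _split_points(c0, c1, pieces, chunk)
        parts = [((r0, r1), (a, b)) for a, b in zip(cuts, cuts[1:])]
    out = []
    for p in parts:
        out.extend(_split_slab(p, max_cells, chunk_shape))
    return out


def plan_requests(rows, cols, chunk_shape=None,
                  waste_ratio: float = DEFAULT_WASTE_RATIO,
                  max_request_cells: int = DEFAULT_MAX_REQUEST_CELLS) -> RequestPlan:
    """Plan rectangular reads for a scattered selection.

    ``rows``/``cols`` are sorted unique 0-based indices.  The plan is
    deterministic: identical inputs yield identical slabs.
    """
    if not (0.0 <= waste_ratio < 1.0):
        raise ValidationError(f"waste_ratio must be in [0, 1), got {waste_ratio}")
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    row_spans = _merge_runs(_coalesce_runs(rows), waste_ratio)
    col_spans = _merge_runs(_coalesce_runs(cols), waste_ratio)
    slabs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for rs in row_spans:
        for cs in col_spans:
            slabs.extend(_split_slab((rs, cs), max_request_cells, chunk_shape))
    gather = np.full((rows.size, cols.size), -1, dtype=np.int64)
    for k, ((r0, r1), (c0, c1)) in enumerate(slabs):
        ri = np.searchsorted(rows, (r0, r1))
        ci = np.searchsorted(cols, (c0, c1))
        gather[ri[0]:ri[1], ci[0]:ci[1]] = k
    return RequestPlan(rows, cols, slabs, gather)


# ---------------------------------------------------------------------------
# HTTP transport

@dataclass
class RemoteDatasetHandle:
    """Identity, geometry and client policy for one remote 2-D dataset.

    Satisfies the seed contract: ``shape``, ``value_kind``, ``chunk_shape``,
    ``read_block`` and planner-backed ``read_selection``.
    """

    base_url: str
    domain: str
    dataset_uuid: str
    shape: tuple[int, int]
    value_kind: str
    chunk_shape: tuple[int, int] | None = None
    timeout_s: float = 10.0
    max_retries: int = 3
    retry_backoff_s: float = 0.25
    waste_ratio: float = DEFAULT_WASTE_RATIO
    max_request_cells: int = DEFAULT_MAX_REQUEST_CELLS

    def read_block(self, row_interval, col_interval) -> np.ndarray:
        (r0, r1), (c0, c1) = row_interval, col_interval
        for lo, hi, extent, axis in ((r0, r1, self.shape[0], "row"),
                                     (c0, c1, self.shape[1], "col")):
            if not (0 <= lo <= hi <= extent):
                raise SelectorError(f"{axis} interval [{lo}, {hi}) outside [0, {extent})")
        if r1 == r0 or c1 == c0:
            return np.empty((r1 - r0, c1 - c0), dtype=np.float64)
        return self._fetch_slab(((r0, r1), (c0, c1)))

    def read_selection(self, rows, cols) -> np.ndarray:
        """Values at sorted-unique ``rows`` × ``cols``, via a request plan."""
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        if rows.size == 0 or cols.size == 0:
            return np.empty((rows.size, cols.size), dtype=np.float64)
        plan = plan_requests(rows, cols, self.chunk_shape,
                             self.waste_ratio, self.max_request_cells)
        out = np.empty((rows.size, cols.size), dtype=np.float64)
        for k, slab in enumerate(plan.slabs):
            block = self._fetch_slab(slab)
            out_r, out_c, loc_r, loc_c = plan.gather_offsets(k)
            out[np.ix_(out_r, out_c)] = block[np.ix_(loc_r, loc_c)]
        return out

    # -- transport internals ------------------------------------------------

    def _get_json(self, path: str, query: dict) -> dict:
        url = f"{self.base_url}{path}?{urllib.parse.urlencode(query)}"
        last_exc: Exception | None = None
        for attempt in range(self.max_retries):
            try:
                with urllib.request.urlopen(url, timeout=self.timeout_s) as resp:
                    logger.info('remote-request method=GET url="%s" status=%d',
                                url, resp.status)
                    return json.loads(resp.read().decode("utf-8"))
            except urllib.error.HTTPError as exc:
                logger.info('remote-request method=GET url="%s" status=%d',
                            url, exc.code)
                if exc.code >= 500:
                    last_exc = exc  # transient server error: retry
                else:
                    raise  # 4xx never retried; caller interprets
            except (urllib.error.URLError, TimeoutError, OSError) as exc:
                last_exc = exc
            if attempt < self.max_retries - 1:
                time.sleep(self.retry_backoff_s * (2 ** attempt))
        raise TransportError(f"GET {url} failed after {self.max_retries} attempts: "
                             f"{last_exc}", status=getattr(last_exc, "code", None))

    def _fetch_slab(self, slab) -> np.ndarray:
        (r0, r1), (c0, c1) = slab
        select = f"[{r0}:{r1},{c0}:{c1}]"
        try:
            payload = self._get_json(
                f"/datasets/{self.dataset_uuid}/value",
                {"domain": self.domain, "select": select},
            )
        except urllib.error.HTTPError as exc:
            if exc.code == 413:
                return self._fetch_split(slab)
            raise TransportError(
                f"value request for slab {slab} rejected with HTTP {exc.code}",
                slab=slab, status=exc.code,
            ) from exc
        except TransportError as exc:
            exc.slab = slab
            raise
        block = np.asarray(payload.get("value"), dtype=np.float64)
        if block.shape != (r1 - r0, c1 - c0):
            raise ProtocolError(
                f"slab {slab}: server returned shape {block.shape}, "
                f"expected {(r1 - r0, c1 - c0)}"
            )
        return block

    def _fetch_split(self, slab) -> np.ndarray:
        """Recover from a 413 by halving the slab along its longer axis."""
        (r0, r1), (c0, c1) = slab
        if (r1 - r0) * (c1 - c0) <= 1:
            raise TransportError(
                f"server rejected a single-cell request for slab {slab}",
                slab=slab, status=413,
            )
        out = np.empty((r1 - r0, c1 - c0), dtype=np.float64)
        if (r1 - r0) >= (c1 - c0):
            mid = (r0 + r1) // 2
            out[: mid - r0] = self._fetch_slab(((r0, mid), (c0, c1)))
            out[mid - r0:] = self._fetch_slab(((mid, r1), (c0, c1)))
        else:
            mid = (c0 + c1) // 2
            out[:, : mid - c0] = self._fetch_slab(((r0, r1), (c0, mid)))
            out[:, mid - c0:] = self._fetch_slab(((r0, r1), (mid, c1)))
        return out


def open_remote_dataset(base_url: str, domain: str, dataset: str,
                        timeout_s: float = 10.0, max_retries: int = 3,
                        retry_backoff_s: float = 0.25) -> RemoteDatasetHandle:
    """Open a handle from metadata endpoints only; no value reads.

    ``dataset`` may be the uuid as listed by the service, or a plain name
    (resolved against the conventional ``ds-<name>`` uuid form).
    """
    probe = RemoteDatasetHandle(base_url, domain, "", (0, 0), "float64",
                                timeout_s=timeout_s, max_retries=max_retries,
                                retry_backoff_s=retry_backoff_s)
    try:
        listing = probe._get_json("/datasets", {"domain": domain})
    except urllib.error.HTTPError as exc:
        raise TransportError(f"domain {domain!r} not found (HTTP {exc.code})",
                             status=exc.code) from exc
    uuids = listing.get("datasets", [])
    if dataset in uuids:
        uuid = dataset
    elif f"ds-{dataset}" in uuids:
        uuid = f"ds-{dataset}"
    else:
        raise TransportError(
            f"dataset {dataset!r} not found in domain {domain!r}; "
            f"service lists {uuids}", status=404,
        )
    try:
        meta = probe._get_json(f"/datasets/{uuid}", {"domain": domain})
    except urllib.error.HTTPError as exc:
        raise TransportError(f"dataset {uuid!r} metadata unavailable "
                             f"(HTTP {exc.code})", status=exc.code) from exc
    dims = meta.get("shape", {}).get("dims", [])
    if len(dims) != 2:
        raise ValidationError(
            f"dataset {uuid!r} is {len(dims)}-D; only 2-D datasets are supported"
        )
    type_class = meta.get("type", {}).get("class", "H5T_FLOAT")
    layout = meta.get("layout") or {}
    chunk_dims = layout.get("dims")
    return RemoteDatasetHandle(
        base_url=base_url, domain=domain, dataset_uuid=uuid,
        shape=(int(dims[0]), int(dims[1])),
        value_kind="int64" if type_class == "H5T_INTEGER" else "float64",
        chunk_shape=tuple(int(d) for d in chunk_dims) if chunk_dims else None,
        timeout_s=timeout_s, max_retries=max_retries,
        retry_backoff_s=retry_backoff_s,
    )


def list_datasets(base_url: str, domain: str, timeout_s: float = 10.0) -> list[str]:
    """Dataset names in a domain (uuids with the ``ds-`` prefix stripped)."""
    probe = RemoteDatasetHandle(base_url, domain, "", (0, 0), "float64",
                                timeout_s=timeout_s)
    try:
        listing = probe._get_json("/datasets", {"domain": domain})
    except urllib.error.HTTPError as exc:
        raise TransportError(f"domain {domain!r} not found (HTTP {exc.code})",
                             status=exc.code) from exc
    return [u[3:] if u.startswith("ds-") else u
            for u in listing.get("datasets", [])]


def fetch_vector(base_url: str, domain: str, dataset: str,
                 timeout_s: float = 10.0) -> list:
    """Fetch a whole 1-D dataset (ID or metadata vector) as a list."""
    probe = RemoteDatasetHandle(base_url, domain, "", (0, 0), "float64",
                                timeout_s=timeout_s)
    uuid = dataset if dataset.startswith("ds-") else f"ds-{dataset}"
    try:
        meta = probe._get_json(f"/datasets/{uuid}", {"domain": domain})
    except urllib.error.HTTPError as exc:
        raise TransportError(f"dataset {dataset!r} not found (HTTP {exc.code})",
                             status=exc.code) from exc
    dims = meta.get("shape", {}).get("dims", [])
    if len(dims) != 1:
        raise ValidationError(f"dataset {dataset!r} is {len(dims)}-D, need 1-D")
    payload = probe._get_json(f"/datasets/{uuid}/value",
                              {"domain": domain, "select": f"[0:{dims[0]}]"})
    return payload.get("value", [])


def build_se_from_hsds(base_url: str, domain: str, assay: str = "assay",
                       **handle_kwargs):
    """Assemble a SummarizedExperiment from a served fixture domain.

    Identifier and metadata vectors (``features``, ``samples``,
    ``row_data.*``, ``col_data.*``) are fetched eagerly — they are small —
    while the assay stays a lazy remote seed: no assay values move until
    realization.  Genomic ranges are attached when the row metadata carries
    ``seqname``/``start``/``end`` columns.
    """
    from .core import FeatureTable, SampleTable, make_se
    from .delayed import DelayedMatrix
    from .ranges import GenomicRanges

    names = list_datasets(base_url, domain)
    handle = open_remote_dataset(base_url, domain, assay, **handle_kwargs)
    feature_ids = [str(v) for v in fetch_vector(base_url, domain, "features")]
    sample_ids = [str(v) for v in fetch_vector(base_url, domain, "samples")]
    row_cols = {n.split(".", 1)[1]: fetch_vector(base_url, domain, n)
                for n in names if n.startswith("row_data.")}
    col_cols = {n.split(".", 1)[1]: fetch_vector(base_url, domain, n)
                for n in names if n.startswith("col_data.")}

    ranges = None
    if {"seqname", "start", "end"}.issubset(row_cols):
        ranges = GenomicRanges(
            tuple(str(s) for s in row_cols.pop("seqname")),
            tuple(int(v) for v in row_cols.pop("start")),
            tuple(int(v) for v in row_cols.pop("end")),
            tuple(str(s) for s in row_cols.pop("strand"))
            if "strand" in row_cols else (),
        )
    row_data = FeatureTable(feature_ids, row_cols or None)
    col_data = SampleTable(sample_ids, col_cols or None)
    return make_se(DelayedMatrix.from_seed(handle), row_data, col_data, ranges)


def read_selection(handle: RemoteDatasetHandle, rows, cols) -> np.ndarray:
    """Dense block in requested order: ``out[i, j] == seed[rows[i], cols[j]]``.

    Rows/cols may be unsorted and contain repeats; the unique sorted
    selection is planned and fetched once, then expanded.
    """
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    if rows.size == 0 or cols.size == 0:
        return np.empty((rows.size, cols.size), dtype=np.float64)
    for idx, extent, axis in ((rows, handle.shape[0], "row"),
                              (cols, handle.shape[1], "col")):
        bad = idx[(idx < 0) | (idx >= extent)]
        if bad.size:
            raise SelectorError(f"{axis} index {bad[0]} out of range [0, {extent})")
    uniq_r, inv_r = np.unique(rows, return_inverse=True)
    uniq_c, inv_c = np.unique(cols, return_inverse=True)
    dense = handle.read_selection(uniq_r, uniq_c)
    return dense[np.ix_(inv_r, inv_c)]
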