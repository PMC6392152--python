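"""In-process mock of the minimal HDF-REST dialect, with a request log.

Serves read-only datasets — from an HDF5 fixture file or plain in-memory
arrays — over the exact endpoints :mod:`lazyse.hsds_client` speaks, on a
local ephemeral port.  The assay is a 2-D numeric dataset; identifier and
metadata vectors (feature/sample IDs, rowData/colData columns) are 1-D
datasets, with nested HDF5 group paths flattened to dotted names
(``row_data/seqname`` → ``row_data.seqname``).

Every request is appended to an append-only log, which is the test surface
for laziness claims: a test can drain the log and assert that, say,
container construction issued no ``/value`` requests at all.

Floats are serialized with round-trip-precision decimal text (Python's
``repr``, which ``json`` uses), so a value survives the JSON round trip
bit-for-bit and oracle comparisons can be exact rather than
tolerance-based.  The server is single-threaded on purpose: the client
contract never requires concurrency, and a deterministic log ordering is
worth more here than throughput.

Dataset uuids are minted deterministically as ``ds-<name>``.
"""

from __future__ import annotations

import json
import re
import threading
import urllib.parse
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, HTTPServer

import numpy as np

from .errors import ValidationError

_SELECT_2D_RE = re.compile(r"^\[(\d+):(\d+),(\d+):(\d+)\]$")
_SELECT_1D_RE = re.compile(r"^\[(\d+):(\d+)\]$")


@dataclass
class RequestRecord:
    method: str
    path: str
    query: dict
    status: int

    @property
    def is_value(self) -> bool:
        return self.path.endswith("/value")


@dataclass
class _Dataset:
    array: np.ndarray
    chunk_shape: tuple[int, int] | None = None

    @property
    def type_class(self) -> str:
        kind = self.array.dtype.kind
        if kind in "OUS":
            return "H5T_STRING"
        if kind in "iu":
            return "H5T_INTEGER"
        return "H5T_FLOAT"


@dataclass
class MockServiceState:
    """Domains → named datasets, plus the append-only request log."""

    domains: dict[str, dict[str, _Dataset]] = field(default_factory=dict)
    request_log: list[RequestRecord] = field(default_factory=list)
    max_request_cells_enforced: int | None = None
    _lock: threading.Lock = field(default_factory=threading.Lock, repr=False)

    def add_dataset(self, domain: str, name: str, array,
                    chunk_shape: tuple[int, int] | None = None):
        arr = np.asarray(array)
        if arr.ndim not in (1, 2):
            raise ValidationError(
                f"mock dataset {name!r} must be 1-D or 2-D, got ndim={arr.ndim}"
            )
        if arr.ndim == 2 and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError(f"2-D mock dataset {name!r} must be numeric")
        if arr.ndim == 2:
            arr = arr.astype(np.float64)
        self.domains.setdefault(domain, {})[name] = _Dataset(arr, chunk_shape)

    def log(self, record: RequestRecord):
        with self._lock:
            self.request_log.append(record)


def _json_value(array: np.ndarray):
    if array.dtype.kind in "OUS":
        return [str(v) for v in array.tolist()]
    return array.tolist()


class _Handler(BaseHTTPRequestHandler):
    state: MockServiceState  # bound by serve()

    def log_message(self, *args):  # silence default stderr chatter
        pass

    def _reply(self, status: int, payload: dict, query: dict):
        body = json.dumps(payload).encode("utf-8")
        # log before replying: a client must never observe its own request
        # as missing from the log it drains right after the response
        self.state.log(RequestRecord(
            "GET", urllib.parse.urlparse(self.path).path, query, status))
        self.send_response(status)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def do_GET(self):
        parsed = urllib.parse.urlparse(self.path)
        query = {k: v[0] for k, v in urllib.parse.parse_qs(parsed.query).items()}
        path = parsed.path

        if path == "/about":
            return self._reply(200, {"api_version": "minimal-1"}, query)

        domain = query.get("domain")
        datasets = self.state.domains.get(domain)

        if path == "/datasets":
            if datasets is None:
                return self._reply(404, {"error": f"unknown domain {domain!r}"}, query)
            return self._reply(
                200, {"datasets": [f"ds-{name}" for name in datasets]}, query)

        m = re.match(r"^/datasets/([^/]+)(/value)?$", path)
        if not m:
            return self._reply(404, {"error": f"no route {path!r}"}, query)
        uuid, want_value = m.group(1), bool(m.group(2))
        if datasets is None:
            return self._reply(404, {"error": f"unknown domain {domain!r}"}, query)
        name = uuid[3:] if uuid.startswith("ds-") else None
        if name is None or name not in datasets:
            return self._reply(404, {"error": f"unknown dataset {uuid!r}"}, query)
        dset = datasets[name]

        if not want_value:
            payload = {
                "shape": {"dims": list(dset.array.shape)},
                "type": {"class": dset.type_class},
                "layout": ({"dims": list(dset.chunk_shape)}
                           if dset.chunk_shape else {}),
            }
            return self._reply(200, payload, query)

        return self._value(dset, query)

    def _value(self, dset: _Dataset, query: dict):
        select = query.get("select", "")
        array = dset.array
        if array.ndim == 2:
            sm = _SELECT_2D_RE.match(select)
            if not sm:
                return self._reply(
                    400, {"error": f"malformed 2-D select {select!r}"}, query)
            r0, r1, c0, c1 = (int(g) for g in sm.groups())
            if not (r0 <= r1 <= array.shape[0] and c0 <= c1 <= array.shape[1]):
                return self._reply(
                    400, {"error": f"select {select} outside shape {array.shape}"},
                    query)
            cells = (r1 - r0) * (c1 - c0)
            sliced = array[r0:r1, c0:c1]
        else:
            sm = _SELECT_1D_RE.match(select)
            if not sm:
                return self._reply(
                    400, {"error": f"malformed 1-D select {select!r}"}, query)
            a, b = (int(g) for g in sm.groups())
            if not a <= b <= array.shape[0]:
                return self._reply(
                    400, {"error": f"select {select} outside shape {array.shape}"},
                    query)
            cells = b - a
            sliced = array[a:b]
        limit = self.state.max_request_cells_enforced
        if limit is not None and cells > limit:
            return self._reply(
                413, {"error": f"selection of {cells} cells exceeds limit {limit}"},
                query)
        return self._reply(200, {"value": _json_value(sliced)}, query)


@dataclass
class MockServiceHandle:
    """A running mock service; ``stop()`` shuts it down."""

    state: MockServiceState
    server: HTTPServer
    thread: threading.Thread

    @property
    def base_url(self) -> str:
        host, port = self.server.server_address[:2]
        return f"http://{host}:{port}"

    @property
    def port(self) -> int:
        return self.server.server_address[1]

    def drain_request_log(self) -> list[RequestRecord]:
        """Return and clear the accumulated request records."""
        with self.state._lock:
            records = list(self.state.request_log)
            self.state.request_log.clear()
        return records

    def stop(self):
        self.server.shutdown()
        self.server.server_close()
        self.thread.join(timeout=5)

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.stop()


def serve(source, domain: str = "/shared/fixture", port: int = 0,
          max_request_cells: int | None = None) -> MockServiceHandle:
    """Start the mock service on localhost.

    ``source`` is either a path to an HDF5 fixture file (every dataset is
    served, nested group paths flattened to dotted names, the file's chunk
    layouts preserved) or a mapping ``{name: array}`` /
    ``{name: (array, chunk_shape)}``.  ``port=0`` picks an ephemeral port.
    ``max_request_cells`` makes the service reject larger value selections
    with 413.
    """
    state = MockServiceState(max_request_cells_enforced=max_request_cells)
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        import h5py

        with h5py.File(source, "r") as f:
            def visit(path, node):
                if isinstance(node, h5py.Dataset) and node.ndim in (1, 2):
                    data = node.asstr()[()] if node.dtype.kind == "O" else node[()]
                    chunks = (tuple(node.chunks)
                              if node.ndim == 2 and node.chunks else None)
                    state.add_dataset(domain, path.replace("/", "."), data, chunks)
            f.visititems(visit)
        if not state.domains.get(domain):
            raise ValidationError(f"no servable datasets found in {source!r}")
    else:
        for name, value in dict(source).items():
            if isinstance(value, tuple):
                array, chunk_shape = value
            else:
                array, chunk_shape = value, None
            state.add_dataset(domain, name, array, chunk_shape)

    handler = type("BoundHandler", (_Handler,), {"state": state})
    try:
        server = HTTPServer(("127.0.0.1", port), handler)
    except OSError as exc:
        raise ValidationError(f"cannot bind mock service to port {port}: {exc}")
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return MockServiceHandle(state, server, thread)
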