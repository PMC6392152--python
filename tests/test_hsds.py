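"""Mock HDF-REST service conformance and remote-seed behaviour."""

import json
import urllib.error
import urllib.request

import numpy as np
import pytest

from lazyse import SelectorError, TransportError, ValidationError
from lazyse.hsds_client import (
    build_se_from_hsds,
    fetch_vector,
    open_remote_dataset,
    read_selection,
)
from lazyse.hsds_mock import serve


@pytest.fixture(scope="module")
def small_service():
    rng = np.random.default_rng(123)
    arrays = {
        "assay": (rng.uniform(0, 100, (100, 60)), (10, 30)),
        "tiny": np.arange(16.0).reshape(4, 4),
        "features": np.array([f"g{i}" for i in range(100)], dtype=object),
    }
    with serve(arrays, domain="/shared/test") as handle:
        yield handle, arrays


def _get(url):
    with urllib.request.urlopen(url) as resp:
        return resp.status, json.loads(resp.read().decode())


def test_about_endpoint(small_service):
    handle, _ = small_service
    status, payload = _get(f"{handle.base_url}/about")
    assert status == 200
    assert payload == {"api_version": "minimal-1"}


def test_metadata_echoes_shape_and_chunks(small_service):
    handle, arrays = small_service
    remote = open_remote_dataset(handle.base_url, "/shared/test", "assay")
    assert remote.shape == (100, 60)
    assert remote.chunk_shape == (10, 30)
    assert remote.value_kind == "float64"
    assert remote.dataset_uuid == "ds-assay"


def test_open_by_uuid_or_name(small_service):
    handle, _ = small_service
    by_name = open_remote_dataset(handle.base_url, "/shared/test", "tiny")
    by_uuid = open_remote_dataset(handle.base_url, "/shared/test", "ds-tiny")
    assert by_name.dataset_uuid == by_uuid.dataset_uuid == "ds-tiny"


def test_missing_domain_and_dataset_are_not_found(small_service):
    handle, _ = small_service
    with pytest.raises(TransportError) as exc:
        open_remote_dataset(handle.base_url, "/no/such", "assay")
    assert exc.value.status == 404
    with pytest.raises(TransportError) as exc:
        open_remote_dataset(handle.base_url, "/shared/test", "nope")
    assert exc.value.status == 404


def test_one_dimensional_dataset_rejected_as_seed(small_service):
    handle, _ = small_service
    with pytest.raises(ValidationError, match="1-D"):
        open_remote_dataset(handle.base_url, "/shared/test", "features")
    assert fetch_vector(handle.base_url, "/shared/test", "features")[:2] == ["g0", "g1"]


def test_value_roundtrip_is_exact(small_service):
    handle, arrays = small_service
    status, payload = _get(
        f"{handle.base_url}/datasets/ds-tiny/value"
        "?domain=%2Fshared%2Ftest&select=[0:2,0:2]")
    assert status == 200
    np.testing.assert_array_equal(np.asarray(payload["value"]),
                                  arrays["tiny"][0:2, 0:2])


def test_malformed_and_out_of_range_selects_get_400(small_service):
    handle, _ = small_service
    for select in ("[0:9999,0:1]", "[0:2]", "nonsense", "[0:1,0:1,0:1]"):
        with pytest.raises(urllib.error.HTTPError) as exc:
            _get(f"{handle.base_url}/datasets/ds-tiny/value"
                 f"?domain=%2Fshared%2Ftest&select={select}")
        assert exc.value.code == 400


def test_read_selection_matches_oracle_and_request_count(small_service):
    handle, arrays = small_service
    remote = open_remote_dataset(handle.base_url, "/shared/test", "assay")
    handle.drain_request_log()
    out = read_selection(remote, [7], list(range(60)))  # one full row
    np.testing.assert_array_equal(out, arrays["assay"][0][[7], :])
    log = [r for r in handle.drain_request_log() if r.is_value]
    assert len(log) == 1  # one run pair, well within the cell budget

    rng = np.random.default_rng(0)
    rows = rng.choice(100, 17, replace=True)
    cols = rng.choice(60, 13, replace=True)
    out = read_selection(remote, rows, cols)
    np.testing.assert_array_equal(out, arrays["assay"][0][np.ix_(rows, cols)])


def test_empty_selection_issues_no_requests(small_service):
    handle, _ = small_service
    remote = open_remote_dataset(handle.base_url, "/shared/test", "assay")
    handle.drain_request_log()
    out = read_selection(remote, [], list(range(60)))
    assert out.shape == (0, 60)
    assert [r for r in handle.drain_request_log() if r.is_value] == []


def test_client_splits_on_413():
    rng = np.random.default_rng(7)
    arr = rng.uniform(size=(30, 20))
    with serve({"assay": arr}, domain="/d", max_request_cells=64) as handle:
        remote = open_remote_dataset(handle.base_url, "/d", "assay")
        out = read_selection(remote, list(range(30)), list(range(20)))
        np.testing.assert_array_equal(out, arr)
        log = handle.drain_request_log()
        assert any(r.status == 413 for r in log)  # server pushed back
        value_ok = [r for r in log if r.is_value and r.status == 200]
        assert value_ok  # and the client recovered by splitting


def test_no_server_side_caching_two_reads_two_entries(small_service):
    handle, _ = small_service
    remote = open_remote_dataset(handle.base_url, "/shared/test", "tiny")
    handle.drain_request_log()
    remote.read_block((0, 2), (0, 2))
    remote.read_block((0, 2), (0, 2))
    assert len([r for r in handle.drain_request_log() if r.is_value]) == 2


def test_retry_then_transport_error_on_dead_server():
    remote_kwargs = dict(timeout_s=0.2, max_retries=2, retry_backoff_s=0.01)
    with pytest.raises(TransportError):
        open_remote_dataset("http://127.0.0.1:9", "/d", "assay", **remote_kwargs)


def test_build_se_from_hsds_round_trip(cohort_fixture, cohort_service):
    se = build_se_from_hsds(cohort_service.base_url, "/shared/fixture")
    assert se.shape == cohort_fixture.matrix.shape
    assert se.feature_ids == cohort_fixture.row_data.ids
    assert "msi_like" in se.col_data.columns
    assert se.row_ranges is not None
    sub = se[["g0005", "g0001"], ["s0002"]]
    np.testing.assert_array_equal(
        sub.realize(),
        cohort_fixture.matrix[np.ix_([5, 1], [2])],
    )
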