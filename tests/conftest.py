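import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lazyse import FeatureTable, SampleTable, make_se
from lazyse.fixtures import FixtureSpec, simulate_counts
from lazyse.ranges import GenomicRanges

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


class InstrumentedSeed:
    """Wraps a seed, recording every read_block rectangle."""

    def __init__(self, inner):
        self.inner = inner
        self.shape = inner.shape
        self.value_kind = inner.value_kind
        self.chunk_shape = inner.chunk_shape
        self.calls = []

    def read_block(self, row_interval, col_interval):
        self.calls.append((tuple(row_interval), tuple(col_interval)))
        return self.inner.read_block(row_interval, col_interval)


def random_ranges(rng, n, chroms=("chr1", "chr2", "chr3"), span=10_000):
    starts = rng.integers(1, span, n)
    lengths = rng.integers(1, 500, n)
    return GenomicRanges(
        tuple(str(rng.choice(chroms)) for _ in range(n)),
        tuple(int(s) for s in starts),
        tuple(int(s + l) for s, l in zip(starts, lengths)),
        tuple(str(rng.choice(["+", "-", "*"])) for _ in range(n)),
    )


def brute_force_overlaps(query, subject, strand_aware=False):
    """All-pairs closed-interval overlap oracle."""
    pairs = []
    for i in range(len(query)):
        for j in range(len(subject)):
            if query.seqnames[i] != subject.seqnames[j]:
                continue
            if query.starts[i] > subject.ends[j] or subject.starts[j] > query.ends[i]:
                continue
            if strand_aware:
                a, b = query.strands[i], subject.strands[j]
                if a != "*" and b != "*" and a != b:
                    continue
            pairs.append((i, j))
    return pairs


def small_se(g=6, n=4, seed=0, with_ranges=True):
    """Tiny eager experiment with sentinel metadata for alignment checks."""
    rng = np.random.default_rng(seed)
    matrix = rng.integers(0, 50, (g, n)).astype(float)
    row_data = FeatureTable(
        [f"g{i}" for i in range(g)],
        {"symbol": [f"S{i}" for i in range(g)], "row_sentinel": list(range(g))},
    )
    col_data = SampleTable(
        [f"s{j}" for j in range(n)], {"col_sentinel": list(range(n))}
    )
    ranges = None
    if with_ranges:
        ranges = GenomicRanges(
            tuple("chr1" if i % 2 == 0 else "chr2" for i in range(g)),
            tuple(1 + 100 * i for i in range(g)),
            tuple(50 + 100 * i for i in range(g)),
        )
    return make_se(matrix, row_data, col_data, ranges), matrix


@pytest.fixture(scope="session")
def cohort_fixture():
    """Default-size cohort fixture (500 x 400), shared across tests."""
    return simulate_counts(FixtureSpec(seed=2026, scenario="cohort_msi"))


@pytest.fixture(scope="session")
def singlecell_fixture():
    return simulate_counts(
        FixtureSpec(n_features=200, n_samples=300, seed=11,
                    scenario="singlecell_panned")
    )


@pytest.fixture(scope="session")
def cohort_h5(cohort_fixture, tmp_path_factory):
    from lazyse.fixtures import write_h5_fixture

    path = tmp_path_factory.mktemp("fix") / "cohort.h5"
    write_h5_fixture(cohort_fixture, path, chunk_shape=(64, 64))
    return path


@pytest.fixture(scope="session")
def cohort_sqlite(cohort_fixture, tmp_path_factory):
    from lazyse.fixtures import write_sql_fixture

    path = tmp_path_factory.mktemp("fix") / "cohort.sqlite"
    write_sql_fixture(cohort_fixture, path, cohort="COAD")
    return path


@pytest.fixture(scope="session")
def cohort_service(cohort_h5):
    from lazyse.hsds_mock import serve

    handle = serve(cohort_h5)
    yield handle
    handle.stop()


def random_selector(rng, extent, max_size=60):
    """Random positions (sometimes with repeats) for oracle-equality draws."""
    size = int(rng.integers(1, min(max_size, extent) + 1))
    replace = bool(rng.integers(0, 2))
    return rng.choice(extent, size=size, replace=replace).astype(np.int64)
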