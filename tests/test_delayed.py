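"""Delayed-matrix view algebra, block realization and laziness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lazyse import DelayedMatrix, InMemorySeed, SelectorError
from lazyse.delayed import TRANSFORMS, HDF5FileSeed

from conftest import InstrumentedSeed


def test_subset_composes_maps_without_reads():
    seed = InstrumentedSeed(InMemorySeed(np.arange(12.0).reshape(3, 4)))
    view = DelayedMatrix(seed, [2, 0, 1], [0, 1, 2, 3])
    sub = view.subset(rows=[1])
    assert sub.row_map.tolist() == [0]
    assert seed.calls == []  # pure view algebra


def test_identity_subset_keeps_maps():
    view = DelayedMatrix.from_array(np.ones((3, 4)))
    same = view.subset(range(3), range(4))
    assert same.row_map.tolist() == view.row_map.tolist()
    assert same.col_map.tolist() == view.col_map.tolist()


def test_out_of_range_subset_names_offender():
    view = DelayedMatrix.from_array(np.ones((3, 4)))
    with pytest.raises(SelectorError, match="5"):
        view.subset(rows=[5])


def test_transform_whitelist():
    view = DelayedMatrix.from_array(np.full((1, 1), 7.0))
    assert view.apply("log2p1").realize()[0, 0] == 3.0  # log2(8)
    assert view.apply("log10p1").subset([0], [0]).realize()[0, 0] == np.log10(8.0)
    assert view.apply("identity").realize()[0, 0] == 7.0
    with pytest.raises(SelectorError, match="log2p1"):
        view.apply("sqrt")


def test_transform_commutes_with_subset():
    rng = np.random.default_rng(3)
    arr = rng.uniform(0, 9, (8, 6))
    view = DelayedMatrix.from_array(arr)
    a = view.apply("log2p1").subset([5, 1], [0, 0, 3])
    b = view.subset([5, 1], [0, 0, 3]).apply("log2p1")
    np.testing.assert_array_equal(a.realize(), b.realize())


def test_empty_view_realizes_without_reads():
    seed = InstrumentedSeed(InMemorySeed(np.ones((4, 4))))
    view = DelayedMatrix(seed, [], [])
    out = view.realize()
    assert out.shape == (0, 0)
    assert seed.calls == []


@pytest.mark.parametrize("block_cells", [1, 7, 64, 10_000])
def test_realize_matches_eager_oracle(block_cells):
    rng = np.random.default_rng(42)
    arr = rng.uniform(0, 100, (50, 40))
    rows = rng.choice(50, 23, replace=True)
    cols = rng.choice(40, 17, replace=True)
    view = DelayedMatrix.from_array(arr).subset(rows, cols).apply("log2p1")
    expected = np.log2(arr[np.ix_(rows, cols)] + 1.0)
    np.testing.assert_array_equal(view.realize(block_cells=block_cells), expected)


def test_single_block_issues_one_read_per_run_pair():
    seed = InstrumentedSeed(InMemorySeed(np.arange(100.0).reshape(10, 10)))
    # rows {0,1,2} and {5}; cols {3} and {7,8}: 2 x 2 run pairs
    view = DelayedMatrix(seed, [5, 0, 1, 2], [8, 3, 7])
    view.realize(block_cells=10_000)
    assert len(seed.calls) == 4
    assert set(seed.calls) == {
        ((0, 3), (3, 4)), ((0, 3), (7, 9)), ((5, 6), (3, 4)), ((5, 6), (7, 9))
    }


def test_no_read_outside_mapped_rows_and_cols():
    seed = InstrumentedSeed(InMemorySeed(np.zeros((30, 30))))
    rows = [4, 9, 9, 2]
    cols = [0, 20, 21]
    DelayedMatrix(seed, rows, cols).realize(block_cells=11)
    for (r0, r1), (c0, c1) in seed.calls:
        assert set(range(r0, r1)) <= set(rows)
        assert set(range(c0, c1)) <= set(cols)


def test_duplicates_replicated_not_refetched():
    seed = InstrumentedSeed(InMemorySeed(np.arange(16.0).reshape(4, 4)))
    view = DelayedMatrix(seed, [1, 1, 1], [2, 2])
    out = view.realize(block_cells=10_000)
    np.testing.assert_array_equal(out, np.full((3, 2), 6.0))
    assert seed.calls == [((1, 2), (2, 3))]  # one fetch of the unique cell


def test_block_iter_tiles_exactly_once():
    rng = np.random.default_rng(1)
    arr = rng.uniform(size=(13, 9))
    view = DelayedMatrix.from_array(arr).subset(rng.choice(13, 11), rng.choice(9, 7))
    for budget in (1, 5, 20, 1000):
        covered = np.zeros(view.shape, dtype=int)
        assembled = np.empty(view.shape)
        for (r0, r1), (c0, c1), block in view.block_iter(budget):
            assert block.shape == (r1 - r0, c1 - c0)
            assert block.size <= max(budget, 1)
            covered[r0:r1, c0:c1] += 1
            assembled[r0:r1, c0:c1] = block
        assert (covered == 1).all()
        np.testing.assert_array_equal(assembled, view.realize())


@given(
    st.lists(st.sampled_from(["subset_rows", "subset_cols", "log2p1", "log10p1"]),
             max_size=6),
    st.integers(0, 2**31 - 1),
)
def test_random_op_chains_match_eager_reference(ops, seed):
    """View algebra is associative/order-preserving vs an eager reference."""
    rng = np.random.default_rng(seed)
    arr = rng.uniform(0, 50, (9, 7))
    view = DelayedMatrix.from_array(arr)
    eager = arr.copy()
    for op in ops:
        if op == "subset_rows" and eager.shape[0]:
            idx = rng.integers(0, eager.shape[0], rng.integers(0, 8))
            view, eager = view.subset(rows=idx), eager[idx, :]
        elif op == "subset_cols" and eager.shape[1]:
            idx = rng.integers(0, eager.shape[1], rng.integers(0, 8))
            view, eager = view.subset(cols=idx), eager[:, idx]
        elif op in TRANSFORMS:
            view, eager = view.apply(op), TRANSFORMS[op](eager)
    assert view.shape == eager.shape
    np.testing.assert_allclose(view.realize(block_cells=13), eager, rtol=1e-12)


def test_hdf5_seed_reads_named_dataset(tmp_path):
    import h5py

    arr = np.arange(30.0).reshape(5, 6)
    path = tmp_path / "m.h5"
    with h5py.File(path, "w") as f:
        f.create_dataset("assay", data=arr, chunks=(2, 3))
    seed = HDF5FileSeed(path, "assay")
    assert seed.shape == (5, 6)
    assert seed.chunk_shape == (2, 3)
    np.testing.assert_array_equal(
        DelayedMatrix.from_seed(seed).subset([4, 0], [5]).realize(),
        arr[np.ix_([4, 0], [5])],
    )
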