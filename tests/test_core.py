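"""Container semantics: construction, X[K,S], overlaps, binding, recipes."""

import numpy as np
import pandas as pd
import pytest

from lazyse import (
    FeatureTable,
    SampleTable,
    SelectorError,
    ValidationError,
    bind_sample_data,
    gene_by_group,
    make_se,
    parse_region,
    resolve_feature,
    subset_by_overlaps,
    subset_se,
)

from conftest import small_se


def test_construction_validates_axes():
    matrix = np.zeros((3, 2))
    rows3 = FeatureTable(["a", "b", "c"])
    cols2 = SampleTable(["x", "y"])
    se = make_se(matrix, rows3, cols2)
    assert se.shape == (3, 2)
    with pytest.raises(ValidationError, match="feature axis"):
        make_se(matrix, FeatureTable(["a", "b"]), cols2)
    with pytest.raises(ValidationError, match="sample axis"):
        make_se(matrix, rows3, SampleTable(["x"]))


def test_duplicate_or_empty_ids_rejected():
    with pytest.raises(ValidationError, match="duplicate"):
        FeatureTable(["a", "a", "b"])
    with pytest.raises(ValidationError, match="non-empty"):
        SampleTable(["x", ""])


def test_metadata_column_length_checked():
    with pytest.raises(ValidationError):
        FeatureTable(["a", "b", "c"], {"symbol": ["s1", "s2"]})


def test_subset_identity_roundtrip():
    se, matrix = small_se()
    same = se[None, None]
    np.testing.assert_array_equal(same.realize(), matrix)
    assert same.feature_ids == se.feature_ids


def test_subset_by_ids_positions_and_mask():
    se, matrix = small_se(g=3, n=2)
    by_id = subset_se(se, ["g2", "g0"], [0])
    np.testing.assert_array_equal(by_id.realize(), matrix[np.ix_([2, 0], [0])])
    assert by_id.feature_ids == ["g2", "g0"]
    assert by_id.sample_ids == ["s0"]
    mask = np.array([True, False, True])
    by_mask = subset_se(se, mask, None)
    np.testing.assert_array_equal(by_mask.realize(), matrix[[0, 2], :])
    dup = subset_se(se, [1, 1], None)  # duplicated positions repeat
    np.testing.assert_array_equal(dup.realize(), matrix[[1, 1], :])
    assert len(dup.row_data) == 2


def test_unresolvable_identifier_named_in_error():
    se, _ = small_se()
    with pytest.raises(SelectorError, match="gX"):
        subset_se(se, ["gX"], None)


def test_subset_composition():
    se, matrix = small_se(g=10, n=8, seed=4)
    rng = np.random.default_rng(0)
    for _ in range(25):
        k1 = rng.integers(0, 10, 6)
        s1 = rng.integers(0, 8, 5)
        k2 = rng.integers(0, 6, 4)
        s2 = rng.integers(0, 5, 3)
        nested = subset_se(subset_se(se, k1, s1), k2, s2)
        direct = subset_se(se, k1[k2], s1[s2])
        np.testing.assert_array_equal(nested.realize(), direct.realize())
        assert nested.feature_ids == direct.feature_ids


def test_metadata_stays_aligned_after_subsetting():
    se, matrix = small_se(g=8, n=5)
    rng = np.random.default_rng(7)
    k = rng.integers(0, 8, 6)
    s = rng.integers(0, 5, 4)
    sub = subset_se(se, k, s)
    # sentinel columns planted at construction equal the chosen positions
    assert sub.row_data["row_sentinel"].tolist() == list(k)
    assert sub.col_data["col_sentinel"].tolist() == list(s)
    assert [sub.row_ranges.starts[i] for i in range(len(k))] == \
        [1 + 100 * int(p) for p in k]
    np.testing.assert_array_equal(sub.realize(), matrix[np.ix_(k, s)])


def test_subset_by_overlaps_keeps_original_order():
    se, _ = small_se(g=6)  # even rows chr1, odd rows chr2
    hit = subset_by_overlaps(se, parse_region("chr1:1-100000"))
    assert hit.feature_ids == ["g0", "g2", "g4"]  # original order retained
    empty = subset_by_overlaps(se, parse_region("chrZ:1-10"))
    assert empty.shape[0] == 0 and empty.shape[1] == se.shape[1]


def test_subset_by_overlaps_requires_ranges():
    se, _ = small_se(with_ranges=False)
    with pytest.raises(ValidationError, match="ranges"):
        subset_by_overlaps(se, parse_region("chr1:1-10"))


def test_bind_sample_data_joins_and_marks_missing():
    se, _ = small_se(g=3, n=4)
    table = pd.DataFrame({"sample": ["s0", "s2"], "msi": [1.5, 7.0]})
    bound = bind_sample_data(se, table, "sample", ["msi"])
    assert bound.col_data["msi"].tolist()[0] == 1.5
    assert np.isnan(bound.col_data["msi"].iloc[1])  # missing marker
    assert bound.shape == se.shape
    # stratification drops the missing half and reports it
    res = gene_by_group(bound, "g0", "msi", ">=", 4.0)
    assert res.n_dropped == 2
    assert sum(v.size for v in res.groups.values()) == 2


def test_bind_sample_data_rejects_collisions_and_duplicate_keys():
    se, _ = small_se()
    with pytest.raises(ValidationError, match="duplicate"):
        bind_sample_data(
            se, pd.DataFrame({"sample": ["s0", "s0"], "v": [1, 2]}), "sample", ["v"])
    with pytest.raises(ValidationError, match="col_sentinel"):
        bind_sample_data(
            se, pd.DataFrame({"sample": ["s0"], "col_sentinel": [9]}),
            "sample", ["col_sentinel"])


def test_gene_by_group_threshold_labels_and_transform():
    matrix = np.array([[0.0, 7.0, 3.0, 15.0]])
    se = make_se(matrix, FeatureTable(["g0"]),
                 SampleTable(["a", "b", "c", "d"], {"score": [1, 5, 2, 9]}))
    res = gene_by_group(se, "g0", "score", ">=", 4, transform="log2p1")
    assert set(res.groups) == {"<4", ">=4"}
    np.testing.assert_array_equal(res.groups["<4"], np.log2([1.0, 4.0]))
    np.testing.assert_array_equal(res.groups[">=4"], np.log2([8.0, 16.0]))
    assert res.groups["<4"][0] == 0.0  # log2(0+1)


def test_gene_by_group_categorical_and_symbol_lookup():
    se, matrix = small_se(g=4, n=4)
    se = bind_sample_data(
        se, pd.DataFrame({"sid": ["s0", "s1", "s2", "s3"],
                          "cls": ["A", "B", "A", "B"]}), "sid", ["cls"])
    res = gene_by_group(se, ("symbol", "S2"), "cls")
    assert res.feature_id == "g2"
    np.testing.assert_array_equal(res.groups["A"], matrix[2, [0, 2]])
    np.testing.assert_array_equal(res.groups["B"], matrix[2, [1, 3]])
    summary = res.summary()
    assert list(summary.columns) == ["group", "n", "mean", "median"]
    assert summary["n"].sum() == 4


def test_gene_by_group_fetches_exactly_one_row():
    from lazyse.delayed import DelayedMatrix, InMemorySeed

    from conftest import InstrumentedSeed

    rng = np.random.default_rng(0)
    seed = InstrumentedSeed(InMemorySeed(rng.uniform(size=(20, 10))))
    se = make_se(DelayedMatrix.from_seed(seed),
                 FeatureTable([f"g{i}" for i in range(20)]),
                 SampleTable([f"s{j}" for j in range(10)],
                             {"grp": ["x", "y"] * 5}))
    gene_by_group(se, "g7", "grp")
    touched_rows = {r for (r0, r1), _ in seed.calls for r in range(r0, r1)}
    assert touched_rows == {7}


def test_resolve_feature_first_match_wins():
    se = make_se(np.zeros((3, 1)),
                 FeatureTable(["a", "b", "c"], {"symbol": ["S", "S", "T"]}),
                 SampleTable(["x"]))
    assert resolve_feature(se, ("symbol", "S")) == 0  # match() semantics
    with pytest.raises(SelectorError):
        resolve_feature(se, ("symbol", "missing"))


def test_unknown_transform_and_comparator_rejected():
    se, _ = small_se()
    with pytest.raises(SelectorError, match="identity"):
        gene_by_group(se, "g0", "col_sentinel", transform="exp")
    with pytest.raises(SelectorError):
        gene_by_group(se, "g0", "col_sentinel", comparator="~", threshold=1)
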