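"""Data reading, cleaning, imputation, standardization and splitting."""

import numpy as np
import pytest

from bfsselect import (
    FeatureTable,
    destandardize,
    drop_missing,
    impute_knn,
    impute_mean,
    read_table,
    standardize,
    stratified_split,
)


def _table(values, labels=None, names=None):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = [i % 2 for i in range(values.shape[0])]
    if names is None:
        names = [f"f{j}" for j in range(values.shape[1])]
    return FeatureTable(values, labels, names)


class TestReadTable:
    def test_parses_numeric_csv(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,b,class\n1,2,1\n3,4,0\n5,6,1\n")
        t = read_table(p)
        assert (t.n, t.d) == (3, 2)
        assert t.feature_names == ["a", "b"]
        assert t.labels.tolist() == [1, 0, 1]

    def test_unparseable_cell_becomes_missing_not_zero(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,b,class\nNaN,2,1\n,4,0\nx,6,1\n")
        t = read_table(p)
        assert np.isnan(t.values[:, 0]).all()
        assert not np.isnan(t.values[:, 1]).any()

    def test_string_labels_mapped_case_insensitively(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,class\n1.0,Normal\n2.0,Abnormal\n")
        t = read_table(p)
        assert t.labels.tolist() == [1, 0]

    def test_missing_label_column_raises(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(KeyError, match="label column"):
            read_table(p)

    def test_nonbinary_labels_named_in_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,class\n1,Normal\n2,weird\n")
        with pytest.raises(ValueError, match="weird"):
            read_table(p)


class TestImputeKnn:
    def test_mean_of_two_nearest_neighbours(self):
        t = _table([[1, 1, np.nan], [1, 1, 4], [1, 1, 6], [10, 10, 100]])
        out = impute_knn(t, k=2)
        assert out.values[0, 2] == pytest.approx(5.0)
        assert not out.has_missing

    def test_no_missing_is_identity(self):
        t = _table([[1, 2], [3, 4]])
        out = impute_knn(t, k=1)
        np.testing.assert_array_equal(out.values, t.values)

    def test_k_equals_all_others_gives_feature_mean(self):
        vals = np.array([[0.0, np.nan], [1.0, 4.0], [2.0, 6.0], [3.0, 11.0]])
        out = impute_knn(_table(vals), k=3)
        assert out.values[0, 1] == pytest.approx(np.mean([4.0, 6.0, 11.0]))

    def test_k1_copies_nearest_neighbour_exactly(self):
        vals = np.array([[0.0, np.nan], [0.1, 42.0], [9.0, 7.0]])
        out = impute_knn(_table(vals), k=1)
        assert out.values[0, 1] == 42.0

    def test_imputed_values_within_donor_range(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 4))
        mask = rng.random(vals.shape) < 0.15
        mask[:, 0] = False  # keep one complete column
        vals[mask] = np.nan
        out = impute_knn(_table(vals), k=5)
        for j in range(4):
            col = vals[:, j]
            observed = col[~np.isnan(col)]
            filled = out.values[np.isnan(col), j]
            assert np.all(filled >= observed.min() - 1e-12)
            assert np.all(filled <= observed.max() + 1e-12)

    def test_feature_missing_everywhere_raises_with_name(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="f1"):
            impute_knn(_table(vals), k=1)

    def test_too_few_neighbours_warns_and_uses_all(self):
        vals = np.array([[1.0, np.nan], [1.5, 4.0], [2.0, 8.0]])
        with pytest.warns(UserWarning, match="eligible neighbours"):
            out = impute_knn(_table(vals), k=10)
        assert out.values[0, 1] == pytest.approx(6.0)

    def test_mean_imputation_uses_observed_feature_mean(self):
        vals = np.array([[1.0, np.nan], [2.0, 4.0], [3.0, 8.0]])
        out = impute_mean(_table(vals))
        assert out.values[0, 1] == pytest.approx(6.0)


class TestDropMissing:
    def test_removes_rows_with_missing_cells(self):
        vals = [[1, 2], [np.nan, 2], [3, 4], [5, np.nan], [7, 8]]
        assert drop_missing(_table(vals)).n == 3

    def test_clean_table_unchanged(self):
        t = _table([[1, 2], [3, 4], [5, 6]])
        out = drop_missing(t)
        np.testing.assert_array_equal(out.values, t.values)

    def test_exact_duplicate_rows_removed(self):
        t = _table([[1, 2], [3, 4], [1, 2], [5, 6]], labels=[0, 1, 0, 1])
        assert drop_missing(t).n == 3

    def test_all_rows_missing_raises(self):
        with pytest.raises(ValueError, match="every sample"):
            drop_missing(_table([[np.nan, 1], [2, np.nan]]))


class TestStandardize:
    def test_population_sd_convention(self):
        _, z = standardize(_table([[1.0], [2.0], [3.0]], labels=[0, 1, 1]))
        np.testing.assert_allclose(z.values.ravel(), [-1.22474487, 0.0, 1.22474487])

    def test_constant_column_maps_to_zero(self):
        _, z = standardize(_table([[5.0], [5.0], [5.0]], labels=[0, 1, 1]))
        np.testing.assert_array_equal(z.values, 0.0)

    def test_train_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        _, z = standardize(_table(rng.normal(3, 7, size=(50, 4))))
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=0), 1.0, atol=1e-9)

    def test_heldout_transformed_with_train_parameters(self):
        train = _table([[0.0], [2.0]])
        other = _table([[4.0], [6.0]])
        params, _, other_z = standardize(train, other)
        np.testing.assert_allclose(other_z.values.ravel(), [3.0, 5.0])
        assert params.mu[0] == 1.0 and params.sigma[0] == 1.0

    def test_roundtrip_recovers_input(self):
        rng = np.random.default_rng(2)
        t = _table(rng.normal(size=(20, 3)))
        params, z = standardize(t)
        np.testing.assert_allclose(destandardize(params, z).values, t.values, atol=1e-9)

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError, match="impute"):
            standardize(_table([[1.0], [np.nan]]))


class TestStratifiedSplit:
    def test_balanced_ten_samples(self):
        t = _table(np.arange(20).reshape(10, 2), labels=[0] * 5 + [1] * 5)
        sp = stratified_split(t, 0.8, seed=0)
        assert (sp.train.n, sp.val.n) == (8, 2)
        assert np.bincount(sp.train.labels).tolist() == [4, 4]
        assert np.bincount(sp.val.labels).tolist() == [1, 1]

    def test_same_seed_same_split(self, tiny_table):
        a = stratified_split(tiny_table, 0.75, seed=5)
        b = stratified_split(tiny_table, 0.75, seed=5)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.val_idx, b.val_idx)

    def test_reference_shape_ratio_preserved(self):
        labels = [0] * 100 + [1] * 210
        t = _table(np.random.default_rng(3).normal(size=(310, 2)), labels=labels)
        sp = stratified_split(t, 0.8, seed=1)
        assert (sp.train.n, sp.val.n) == (248, 62)
        # per-class proportions within one sample
        assert abs(np.sum(sp.train.labels == 1) - 168) <= 1
        assert abs(np.sum(sp.val.labels == 1) - 42) <= 1

    def test_indices_partition_rows(self, tiny_table):
        sp = stratified_split(tiny_table, 0.5, seed=9)
        union = np.sort(np.concatenate([sp.train_idx, sp.val_idx]))
        np.testing.assert_array_equal(union, np.arange(tiny_table.n))

    def test_small_class_rejected(self):
        t = _table([[1.0], [2.0], [3.0]], labels=[0, 0, 1])
        with pytest.raises(ValueError, match="at least 2"):
            stratified_split(t, 0.5, seed=0)
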