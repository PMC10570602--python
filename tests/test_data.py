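import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lassonet_rnn.data import (
    NormalizationStats,
    TimeSeriesDataset,
    apply_normalizer,
    drop_sparse_subjects,
    fit_normalizer,
    impute_missing,
    invert_normalizer,
    read_long_csv,
    read_ts_file,
    read_wide_csv,
    train_test_split,
    write_long_csv,
    write_ts_file,
)
from lassonet_rnn.synthetic import SyntheticSpec, generate

from conftest import random_dataset


# ---------------------------------------------------------------------------
# TimeSeriesDataset invariants
# ---------------------------------------------------------------------------


class TestDatasetInvariants:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            TimeSeriesDataset(
                values=np.zeros((2, 3, 2)),
                mask=np.ones((2, 3, 3), dtype=bool),
                feature_names=("a", "b"),
                time_labels=(0, 1, 2),
            )

    def test_duplicate_feature_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            TimeSeriesDataset(
                values=np.zeros((1, 1, 2)),
                mask=np.ones((1, 1, 2), dtype=bool),
                feature_names=("a", "a"),
                time_labels=(0,),
            )

    def test_nonfinite_observed_value_rejected(self):
        values = np.zeros((1, 1, 1))
        values[0, 0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            TimeSeriesDataset(
                values=values,
                mask=np.ones((1, 1, 1), dtype=bool),
                feature_names=("a",),
                time_labels=(0,),
            )

    def test_nonfinite_masked_value_ignored(self):
        values = np.zeros((1, 2, 1))
        values[0, 1, 0] = np.nan
        mask = np.array([[[True], [False]]])
        ds = TimeSeriesDataset(values=values, mask=mask, feature_names=("a",), time_labels=(0, 1))
        assert ds.n_subjects == 1

    def test_label_length_checked(self):
        with pytest.raises(ValueError, match="length-N"):
            TimeSeriesDataset(
                values=np.zeros((2, 1, 1)),
                mask=np.ones((2, 1, 1), dtype=bool),
                feature_names=("a",),
                time_labels=(0,),
                labels=np.array([1]),
            )

    @given(st.integers(1, 6), st.integers(1, 4), st.integers(1, 5), st.integers(0, 2**31))
    @settings(max_examples=30, deadline=None)
    def test_random_datasets_satisfy_invariants(self, n, q, m, seed):
        ds = random_dataset(np.random.default_rng(seed), n=n, q=q, m=m, missing_rate=0.3)
        assert ds.shape == (n, q, m)
        assert ds.values.shape == ds.mask.shape
        assert len(set(ds.feature_names)) == m
        assert np.all(np.isfinite(ds.values[ds.mask]))


# ---------------------------------------------------------------------------
# long CSV
# ---------------------------------------------------------------------------


class TestLongCSV:
    def _write(self, tmp_path, rows, columns):
        p = tmp_path / "panel.csv"
        pd.DataFrame(rows, columns=columns).to_csv(p, index=False)
        return p

    def test_complete_panel(self, tmp_path):
        rows = [
            ["s1", t, 1.0 * t, 2.0 * t, 0] for t in (2013, 2015, 2018)
        ] + [["s2", t, 3.0, 4.0, 1] for t in (2013, 2015, 2018)]
        p = self._write(tmp_path, rows, ["id", "time", "x", "y", "label"])
        ds = read_long_csv(p, "id", "time", ["x", "y"], "label")
        assert ds.shape == (2, 3, 2)
        assert ds.mask.all()
        assert ds.labels.tolist() == [0, 1]
        assert ds.subject_ids == ("s1", "s2")

    def test_missing_wave_masked(self, tmp_path):
        rows = [["A", 0, 1.0, 0], ["A", 2, 2.0, 0], ["B", 0, 3.0, 1], ["B", 1, 4.0, 1], ["B", 2, 5.0, 1]]
        p = self._write(tmp_path, rows, ["id", "time", "x", "label"])
        ds = read_long_csv(p, "id", "time", ["x"], "label")
        assert ds.shape == (2, 3, 1)
        assert not ds.mask[0, 1].any()  # A absent at wave 1
        assert ds.mask[0, 0].all() and ds.mask[0, 2].all()

    def test_duplicate_pair_is_hard_error(self, tmp_path):
        rows = [["A", 0, 1.0], ["A", 0, 2.0]]
        p = self._write(tmp_path, rows, ["id", "time", "x"])
        with pytest.raises(ValueError, match=r"duplicate \(id, time\) pair.*A"):
            read_long_csv(p, "id", "time", ["x"])

    def test_conflicting_labels_hard_error(self, tmp_path):
        rows = [["A", 0, 1.0, 0], ["A", 1, 1.0, 1]]
        p = self._write(tmp_path, rows, ["id", "time", "x", "label"])
        with pytest.raises(ValueError, match="conflicting labels.*A"):
            read_long_csv(p, "id", "time", ["x"], "label")

    def test_charls_scale_panel(self, tmp_path):
        # synthetic stand-in for the real 3887-subject, 3-wave, 27-variable panel
        spec = SyntheticSpec(n_subjects=3887, n_waves=3, n_features=27, seed=7,
                             missing_rate=0.02)
        ds, _ = generate(spec)
        p = tmp_path / "charls_like.csv"
        write_long_csv(ds, p)
        back = read_long_csv(p, "id", "time", list(ds.feature_names), "label")
        assert back.shape == (3887, 3, 27)
        np.testing.assert_array_equal(back.labels, ds.labels)
        np.testing.assert_array_equal(back.mask, ds.mask)
        np.testing.assert_allclose(back.values[back.mask], ds.values[ds.mask])


class TestWideCSV:
    def test_round_trip_shape(self, tmp_path):
        df = pd.DataFrame(
            {
                "id": [1, 2],
                "x__2013": [1.0, 2.0],
                "x__2015": [3.0, 4.0],
                "y__2013": [5.0, 6.0],
                "y__2015": [7.0, 8.0],
                "label": [0, 1],
            }
        )
        p = tmp_path / "wide.csv"
        df.to_csv(p, index=False)
        ds = read_wide_csv(p)
        assert ds.shape == (2, 2, 2)
        assert ds.feature_names == ("x", "y")
        assert ds.labels.tolist() == [0, 1]
        assert ds.values[1, 1, 1] == 8.0


# ---------------------------------------------------------------------------
# .ts format
# ---------------------------------------------------------------------------


TOY_TS = """\
@problemName toy
@timeStamps false
@univariate false
@classLabel true 0 1
@data
1.0,2.0,3.0:4.0,5.0,6.0:0
7.0,8.0,9.0:10.0,11.0,12.0:1
"""


class TestTsFormat:
    def test_toy_parse(self, tmp_path):
        p = tmp_path / "toy.ts"
        p.write_text(TOY_TS)
        ds = read_ts_file(p)
        assert ds.shape == (2, 3, 2)
        assert ds.labels.tolist() == [0, 1]
        assert ds.values[0, 0, 0] == 1.0 and ds.values[0, 0, 1] == 4.0
        assert ds.values[1, 2, 0] == 9.0

    def test_class_label_header_maps_to_01(self, tmp_path):
        p = tmp_path / "toy.ts"
        p.write_text(TOY_TS)
        assert set(read_ts_file(p).labels.tolist()) == {0, 1}

    def test_unknown_tag_warns_and_skips(self, tmp_path):
        p = tmp_path / "toy.ts"
        p.write_text("@mysteryTag hello\n" + TOY_TS)
        with pytest.warns(UserWarning, match="mysterytag"):
            ds = read_ts_file(p)
        assert ds.shape == (2, 3, 2)

    def test_ragged_series_hard_error(self, tmp_path):
        p = tmp_path / "bad.ts"
        p.write_text("@data\n1.0,2.0:3.0,4.0:0\n1.0:2.0,3.0:1\n")
        with pytest.raises(ValueError, match="ragged"):
            read_ts_file(p)

    def test_round_trip(self, tmp_path, rng):
        ds = random_dataset(rng, n=5, q=4, m=3)
        p = tmp_path / "rt.ts"
        write_ts_file(ds, p)
        back = read_ts_file(p)
        np.testing.assert_allclose(back.values, ds.values)
        np.testing.assert_array_equal(back.labels, ds.labels)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


class TestImpute:
    def _with_missing(self):
        values = np.array([[[1.0], [0.0], [3.0]], [[5.0], [6.0], [7.0]]])
        mask = np.ones_like(values, dtype=bool)
        mask[0, 1, 0] = False
        return TimeSeriesDataset(values=values, mask=mask, feature_names=("x",),
                                 time_labels=(0, 1, 2))

    def test_feature_mean_fill(self):
        # observed {1, 3, 5, 6, 7}: mean 4.4
        out = impute_missing(self._with_missing(), "feature_mean")
        assert out.mask.all()
        assert out.values[0, 1, 0] == pytest.approx(4.4)

    def test_feature_mean_two_point_example(self):
        values = np.array([[[1.0], [0.0]], [[3.0], [3.0]]])
        mask = np.array([[[True], [False]], [[True], [True]]])
        ds = TimeSeriesDataset(values=values, mask=mask, feature_names=("x",), time_labels=(0, 1))
        # mean over observed cells {1, 3, 3} is 7/3; restrict to {1,3}:
        mask2 = np.array([[[True], [False]], [[True], [False]]])
        ds2 = TimeSeriesDataset(values=values, mask=mask2, feature_names=("x",), time_labels=(0, 1))
        assert impute_missing(ds2).values[0, 1, 0] == pytest.approx(2.0)

    def test_no_missing_is_identity(self, small_dataset):
        out = impute_missing(small_dataset)
        assert out is small_dataset

    def test_carry_forward(self):
        values = np.array([[[5.0], [0.0], [0.0]]])
        mask = np.array([[[True], [False], [False]]])
        ds = TimeSeriesDataset(values=values, mask=mask, feature_names=("x",), time_labels=(0, 1, 2))
        out = impute_missing(ds, "carry_forward")
        assert out.values[0, 1, 0] == 5.0
        assert out.values[0, 2, 0] == 5.0

    def test_carry_forward_wave0_falls_back_to_mean(self):
        values = np.array([[[0.0], [2.0]], [[4.0], [4.0]]])
        mask = np.array([[[False], [True]], [[True], [True]]])
        ds = TimeSeriesDataset(values=values, mask=mask, feature_names=("x",), time_labels=(0, 1))
        out = impute_missing(ds, "carry_forward")
        assert out.values[0, 0, 0] == pytest.approx(np.mean([2.0, 4.0, 4.0]))

    def test_constant_fill(self):
        out = impute_missing(self._with_missing(), "constant", fill_value=-9.0)
        assert out.values[0, 1, 0] == -9.0

    def test_fully_missing_feature_hard_error(self):
        values = np.zeros((2, 2, 2))
        mask = np.ones_like(values, dtype=bool)
        mask[:, :, 1] = False
        ds = TimeSeriesDataset(values=values, mask=mask, feature_names=("x", "y"),
                               time_labels=(0, 1))
        with pytest.raises(ValueError, match="'y'"):
            impute_missing(ds, "feature_mean")

    def test_shape_preserved(self, rng):
        ds = random_dataset(rng, n=6, q=3, m=4, missing_rate=0.4)
        assert impute_missing(ds).shape == ds.shape


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


class TestNormalizer:
    def test_two_point_zscore(self):
        values = np.array([[[0.0]], [[2.0]]])
        ds = TimeSeriesDataset(values=values, mask=np.ones_like(values, dtype=bool),
                               feature_names=("x",), time_labels=(0,))
        out = apply_normalizer(ds, fit_normalizer(ds))
        np.testing.assert_allclose(sorted(out.values.ravel()), [-1.0, 1.0])

    def test_constant_feature(self):
        values = np.full((3, 2, 1), 7.0)
        ds = TimeSeriesDataset(values=values, mask=np.ones_like(values, dtype=bool),
                               feature_names=("x",), time_labels=(0, 1))
        stats = fit_normalizer(ds)
        assert stats.scale[0] == 1.0
        assert np.all(apply_normalizer(ds, stats).values == 0.0)

    def test_inverse_round_trip(self, rng):
        ds = random_dataset(rng, n=10, q=3, m=4)
        stats = fit_normalizer(ds)
        back = invert_normalizer(apply_normalizer(ds, stats), stats)
        np.testing.assert_allclose(back.values, ds.values, atol=1e-10)

    def test_normalized_train_moments(self, rng):
        ds = random_dataset(rng, n=50, q=3, m=6)
        out = apply_normalizer(ds, fit_normalizer(ds))
        flat = out.values.reshape(-1, 6)
        np.testing.assert_allclose(flat.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(flat.var(axis=0), 1.0, atol=1e-8)

    def test_dimension_mismatch_hard_error(self, rng):
        ds = random_dataset(rng, n=4, q=2, m=3)
        stats = NormalizationStats(location=np.zeros(5), scale=np.ones(5))
        with pytest.raises(ValueError):
            apply_normalizer(ds, stats)

    def test_requires_imputed(self, rng):
        ds = random_dataset(rng, n=5, q=2, m=2, missing_rate=0.5)
        with pytest.raises(ValueError, match="missing"):
            fit_normalizer(ds)

    def test_minmax(self, rng):
        ds = random_dataset(rng, n=10, q=2, m=3)
        out = apply_normalizer(ds, fit_normalizer(ds, "minmax"))
        assert out.values.min() == pytest.approx(0.0)
        assert out.values.max() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------


class TestSplit:
    def test_80_20_sizes(self, rng):
        ds = random_dataset(rng, n=10, q=2, m=2)
        train, test = train_test_split(ds, 0.8, seed=0)
        assert train.n_subjects == 8
        assert test.n_subjects == 2

    def test_deterministic(self, rng):
        ds = random_dataset(rng, n=30, q=2, m=2)
        a1, b1 = train_test_split(ds, 0.8, seed=3)
        a2, b2 = train_test_split(ds, 0.8, seed=3)
        np.testing.assert_array_equal(a1.values, a2.values)
        np.testing.assert_array_equal(b1.labels, b2.labels)

    def test_partition_property(self, rng):
        ds = random_dataset(rng, n=23, q=2, m=2)
        ds = TimeSeriesDataset(values=ds.values, mask=ds.mask, feature_names=ds.feature_names,
                               time_labels=ds.time_labels, labels=ds.labels,
                               subject_ids=tuple(range(23)))
        train, test = train_test_split(ds, 0.7, seed=1)
        ids = set(train.subject_ids) | set(test.subject_ids)
        assert ids == set(range(23))
        assert not set(train.subject_ids) & set(test.subject_ids)

    def test_stratification_keeps_both_classes(self):
        values = np.zeros((10, 2, 1))
        labels = np.array([1, 1] + [0] * 8)
        ds = TimeSeriesDataset(values=values, mask=np.ones_like(values, dtype=bool),
                               feature_names=("x",), time_labels=(0, 1), labels=labels)
        for seed in range(5):
            train, test = train_test_split(ds, 0.8, seed=seed)
            assert 1 in train.labels and 1 in test.labels

    def test_bad_fraction_hard_error(self, small_dataset):
        for frac in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                train_test_split(small_dataset, frac, seed=0)

    def test_unlabeled_hard_error(self, rng):
        ds = random_dataset(rng, labeled=False)
        with pytest.raises(ValueError, match="label"):
            train_test_split(ds, 0.8, seed=0)


def test_drop_sparse_subjects(rng):
    ds = random_dataset(rng, n=10, q=3, m=4, missing_rate=0.0)
    mask = ds.mask.copy()
    mask[0] = False  # subject 0 fully missing
    ds = TimeSeriesDataset(values=ds.values, mask=mask, feature_names=ds.feature_names,
                           time_labels=ds.time_labels, labels=ds.labels)
    assert drop_sparse_subjects(ds, 1.0).n_subjects == 10
    assert drop_sparse_subjects(ds, 0.5).n_subjects == 9
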