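"""Data loading, min-max normalization, synthetic generation, partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppfil.data import (
    DataError,
    NormalizationParams,
    SyntheticSpec,
    TabularDataset,
    apply_minmax,
    fit_minmax,
    generate_synthetic_tabular,
    generate_task_stream,
    partition_clients,
    train_test_split,
)


def _ds(columns, labels=None):
    arr = np.asarray(columns, dtype=float)
    labels = np.zeros(arr.shape[0], int) if labels is None else labels
    return TabularDataset(arr, labels, [f"f{i}" for i in range(arr.shape[1])])


class TestMinMax:
    def test_fit_reads_off_extremes(self):
        params = fit_minmax(_ds([[2], [4], [6]]))
        assert params.mins[0] == 2 and params.maxs[0] == 6

    def test_constant_column_flagged_degenerate(self):
        params = fit_minmax(_ds([[5], [5], [5]]))
        assert params.mins[0] == params.maxs[0] == 5
        assert params.degenerate[0]

    def test_per_feature_extremes(self):
        params = fit_minmax(_ds([[0, 10], [1, 20]]))
        assert list(params.mins) == [0, 10] and list(params.maxs) == [1, 20]

    def test_endpoint_mapping(self):
        out = apply_minmax(_ds([[2], [4], [6]]), NormalizationParams([2], [6]))
        assert np.allclose(out.features.ravel(), [0.0, 0.5, 1.0])

    def test_degenerate_column_maps_to_zero(self):
        out = apply_minmax(_ds([[5], [5], [5]]), NormalizationParams([5], [5]))
        assert np.all(out.features == 0.0)

    def test_out_of_range_clipped(self):
        out = apply_minmax(_ds([[8]]), NormalizationParams([2], [6]))
        assert out.features[0, 0] == 1.0

    def test_arity_mismatch_rejected(self):
        with pytest.raises(DataError):
            apply_minmax(_ds([[1, 2]]), NormalizationParams([0], [1]))

    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            fit_minmax(_ds(np.empty((0, 2))))

    def test_normalization_idempotent_once_fitted_to_unit_scale(self):
        # after normalizing, re-fitting on the output yields (0, 1) bounds
        # and a second application is the identity
        data = _ds([[2.0], [9.0], [-3.0], [4.0]])
        once = apply_minmax(data, fit_minmax(data))
        params2 = fit_minmax(once)
        twice = apply_minmax(once, params2)
        assert np.allclose(once.features, twice.features)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_normalized_values_in_unit_interval(self, column):
        ds = _ds([[v] for v in column])
        out = apply_minmax(ds, fit_minmax(ds))
        assert np.all((out.features >= 0.0) & (out.features <= 1.0))


class TestSyntheticGenerator:
    def test_seeded_determinism(self):
        spec = SyntheticSpec(n_samples=50, m_features=6, k_informative=2, seed=3)
        a = generate_synthetic_tabular(spec)
        b = generate_synthetic_tabular(spec)
        assert np.array_equal(a.features, b.features)
        assert np.array_equal(a.labels, b.labels)

    def test_null_effect_gives_exchangeable_features(self):
        spec = SyntheticSpec(
            n_samples=4000, m_features=6, k_informative=3, effect_size=0.0,
            ordinal_fraction=0.0, seed=5,
        )
        ds = generate_synthetic_tabular(spec)
        d0 = ds.features[ds.labels == 1, 0].mean() - ds.features[ds.labels == 0, 0].mean()
        assert abs(d0) < 4 / np.sqrt(2000)  # no class separation anywhere

    def test_effect_size_matches_stated_moments(self):
        spec = SyntheticSpec(
            n_samples=600, m_features=20, k_informative=5, effect_size=1.5, seed=11
        )
        ds = generate_synthetic_tabular(spec)
        x1 = ds.features[ds.labels == 1]
        x0 = ds.features[ds.labels == 0]
        n1, n0 = len(x1), len(x0)
        se = np.sqrt(1.0 / n1 + 1.0 / n0)  # sd of the mean difference, sd=1
        for j in range(5):
            diff = x1[:, j].mean() - x0[:, j].mean()
            assert abs(diff - 1.5) < 3 * se

    def test_invalid_spec_rejected(self):
        with pytest.raises(DataError):
            SyntheticSpec(m_features=3, k_informative=5)
        with pytest.raises(DataError):
            SyntheticSpec(effect_size=-1)

    def test_multiclass_means_pairwise_separated(self):
        spec = SyntheticSpec(
            n_samples=4000, m_features=10, k_informative=5, effect_size=2.0,
            class_count=4, ordinal_fraction=0.0, seed=2,
        )
        ds = generate_synthetic_tabular(spec)
        means = np.stack([ds.features[ds.labels == c, :5].mean(axis=0) for c in range(4)])
        for a in range(4):
            for b in range(a + 1, 4):
                # codewords differ in >= ceil(k/2)=3 coords, each by effect*sd
                assert np.sum(np.abs(means[a] - means[b]) > 1.0) >= 3


class TestTaskStream:
    def test_class_incremental_disjoint_label_groups(self):
        base = SyntheticSpec(n_samples=200, m_features=5, k_informative=2, class_count=4, seed=0)
        stream = generate_task_stream(base, 2, mode="class")
        assert set(np.unique(stream.tasks[0].labels)) == {0, 1}
        assert set(np.unique(stream.tasks[1].labels)) == {2, 3}

    def test_union_of_task_labels_covers_all_classes(self):
        base = SyntheticSpec(n_samples=300, m_features=5, k_informative=3, class_count=6, seed=0)
        stream = generate_task_stream(base, 3, mode="class")
        assert set(stream.all_classes) == set(range(6))

    def test_domain_incremental_null_shift_is_iid(self):
        base = SyntheticSpec(n_samples=3000, m_features=5, k_informative=2, seed=0,
                             ordinal_fraction=0.0)
        stream = generate_task_stream(base, 2, mode="domain", domain_shift=0.0)
        m0 = stream.tasks[0].features[:, 0].mean()
        m1 = stream.tasks[1].features[:, 0].mean()
        assert abs(m0 - m1) < 0.15  # same distribution, independent draws

    def test_insufficient_classes_rejected(self):
        base = SyntheticSpec(n_samples=100, m_features=4, k_informative=2, class_count=2)
        with pytest.raises(DataError):
            generate_task_stream(base, 3, mode="class")


class TestPartitioning:
    def test_iid_even_split(self):
        ds = _ds(np.random.default_rng(0).normal(size=(100, 3)))
        part = partition_clients(ds, 4, "iid", seed=0)
        assert sorted(len(v) for v in part.indices.values()) == [25, 25, 25, 25]

    def test_per_class_quota_ten_percent(self):
        labels = np.repeat([0, 1], 200)
        ds = _ds(np.zeros((400, 2)), labels)
        part = partition_clients(ds, 10, "per-class-quota", seed=0, quota=0.1)
        for idx in part.indices.values():
            counts = np.bincount(labels[idx], minlength=2)
            assert list(counts) == [20, 20]

    def test_partition_conservation(self):
        ds = _ds(np.random.default_rng(1).normal(size=(103, 2)),
                 np.random.default_rng(1).integers(0, 2, 103))
        for scheme in ("iid", "dirichlet"):
            part = partition_clients(ds, 5, scheme, seed=2)
            joined = np.concatenate(list(part.indices.values()))
            assert len(joined) == len(np.unique(joined))
            assert part.total <= 103

    def test_dirichlet_concentration_limit(self):
        # alpha -> infinity: client class proportions approach global ones
        labels = np.repeat([0, 1], 500)
        ds = _ds(np.zeros((1000, 1)), labels)
        part = partition_clients(ds, 4, "dirichlet", seed=3, alpha=1e6)
        for idx in part.indices.values():
            frac1 = labels[idx].mean()
            assert abs(frac1 - 0.5) < 0.05

    def test_infeasible_quota_rejected(self):
        labels = np.array([0] * 3 + [1] * 3)
        ds = _ds(np.zeros((6, 1)), labels)
        with pytest.raises(DataError):
            partition_clients(ds, 10, "per-class-quota", seed=0, quota=0.1)


class TestRoundTripAndSplit:
    def test_csv_round_trip(self, tmp_path):
        spec = SyntheticSpec(n_samples=30, m_features=4, k_informative=2, seed=9)
        ds = generate_synthetic_tabular(spec)
        path = tmp_path / "data.csv"
        ds.to_csv(path)
        back = TabularDataset.from_csv(path)
        assert np.allclose(ds.features, back.features)
        assert np.array_equal(ds.labels, back.labels)
        assert ds.feature_names == back.feature_names

    def test_missing_values_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,target\n1.0,,0\n2.0,3.0,1\n")
        with pytest.raises(DataError):
            TabularDataset.from_csv(path)

    def test_stratified_split_fractions(self):
        spec = SyntheticSpec(n_samples=200, m_features=4, k_informative=2, seed=0)
        ds = generate_synthetic_tabular(spec)
        train, test = train_test_split(ds, 0.2, seed=0)
        assert train.n_samples + test.n_samples == 200
        for c in ds.classes:
            total = (ds.labels == c).sum()
            in_test = (test.labels == c).sum()
            assert abs(in_test - 0.2 * total) <= 1
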