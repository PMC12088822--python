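"""Preprocessing operations against hand-computed and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdbncaen import synthdata
from hdbncaen.data import Feature, FeatureSchema, LabeledDataset
from hdbncaen.preprocess import (
    Imputer, Preprocessor, ScalerParams, augment_images, chi_square_score,
    derive_bmi, encode, fit_scaler, flag_outliers, impute, pca_transform,
    rfe_select, scale, stratified_split,
)
from hdbncaen.synthdata import SynthSpec


def _tiny(numeric, categorical=None, y=None):
    feats = [Feature("x", "numeric")]
    cols = {"x": np.asarray(numeric, dtype=float)}
    if categorical is not None:
        feats.append(Feature("c", "categorical-nominal", levels=("a", "b")))
        cols["c"] = np.asarray(categorical, dtype=object)
    n = len(numeric)
    return LabeledDataset(pd.DataFrame(cols), y if y is not None else np.zeros(n, int),
                          FeatureSchema(tuple(feats)))


class TestImpute:
    def test_numeric_median_fill(self):
        ds = _tiny([1.0, np.nan, 3.0, 100.0])
        out = impute(ds, ds.schema)
        assert out.frame["x"][1] == 3.0  # median of {1, 3, 100}

    def test_categorical_mode_fill_with_tie_break(self):
        ds = _tiny([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", np.nan])
        out = impute(ds, ds.schema)
        assert out.frame["c"][3] == "a"
        ds = _tiny([1.0, 1.0, 1.0, 1.0], ["b", "a", np.nan, np.nan])
        assert impute(ds, ds.schema).frame["c"][2] == "a"  # tie -> smallest

    def test_identity_and_idempotence(self):
        ds = _tiny([1.0, 2.0, 3.0, 4.0], ["a", "b", "a", "b"])
        once = impute(ds, ds.schema)
        pd.testing.assert_frame_equal(once.frame, ds.frame)
        twice = impute(once, ds.schema)
        pd.testing.assert_frame_equal(twice.frame, once.frame)

    def test_fully_missing_feature_is_named(self):
        ds = _tiny([np.nan, np.nan, np.nan, np.nan])
        with pytest.raises(ValueError, match="'x'"):
            impute(ds, ds.schema)

    def test_knn_fills_timeseries_from_nearest_rows(self):
        feats = (Feature("x", "numeric"), Feature("s", "timeseries", length=2))
        frame = pd.DataFrame({
            "x":    [0.0, 0.1, 10.0, 10.1, 0.05],
            "s_t0": [1.0, 1.2, 9.0, 9.2, np.nan],
            "s_t1": [1.1, 1.3, 9.1, 9.3, 1.0],
        })
        ds = LabeledDataset(frame, np.zeros(5, int), FeatureSchema(feats))
        out = Imputer(ds.schema, k=2).fit(ds).transform(ds)
        # nearest complete rows to x=0.05 are the x≈0 donors, not the x≈10 ones
        assert out.frame["s_t0"][4] == pytest.approx(1.1)


class TestOutliers:
    def test_zscore_strict_boundary(self):
        x = [1.0] * 9 + [11.0]  # population sd 3, Z(11) = 3 exactly
        assert not flag_outliers(x, "zscore", 3.0).any()
        x = [1.0] * 9 + [11.5]
        assert flag_outliers(x, "zscore", 3.0)[-1]

    def test_iqr_hand_quartiles(self):
        x = list(range(1, 9)) + [100]  # Q1=3, Q3=7, fences [-3, 13]
        flags = flag_outliers(x, "iqr")
        assert flags.tolist() == [False] * 8 + [True]

    def test_mean_value_never_flagged(self):
        x = np.array([2.0, 4.0, 6.0])  # middle value equals the mean
        assert not flag_outliers(x, "zscore", 0.5)[1]

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            flag_outliers([5.0, 5.0, 5.0], "zscore")


class TestScaling:
    def test_minmax(self):
        p = fit_scaler([0.0, 5.0, 10.0])
        assert scale([0, 5, 10], "minmax", p).tolist() == [0.0, 0.5, 1.0]

    def test_standard_population_sd(self):
        p = fit_scaler([1.0, 2.0, 3.0])
        out = scale([1, 2, 3], "standard", p)
        assert out == pytest.approx([-1.2247448, 0.0, 1.2247448], abs=1e-6)

    def test_no_clipping_outside_training_range(self):
        p = fit_scaler([0.0, 10.0])
        assert scale([20.0], "minmax", p)[0] == 2.0

    def test_degenerate_feature_rejected(self):
        with pytest.raises(ValueError):
            scale([1.0], "minmax", ScalerParams(2.0, 2.0, 2.0, 0.0))


class TestEncode:
    def test_nominal_keeps_all_levels(self):
        out = encode(["a", "b"], "nominal", ["a", "b"])
        assert out.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_ordinal_rank_order(self):
        out = encode(["low", "high", "low"], "ordinal", ["low", "med", "high"])
        assert out.ravel().tolist() == [0.0, 2.0, 0.0]

    def test_single_level_constant_column(self):
        assert encode(["a", "a"], "nominal", ["a"]).tolist() == [[1.0], [1.0]]

    def test_unseen_category_named_in_error(self):
        with pytest.raises(ValueError, match="'z'"):
            encode(["z"], "nominal", ["a", "b"])

    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=30)
    def test_one_hot_rows_sum_to_one(self, xs):
        out = encode(xs, "nominal", ["a", "b", "c"])
        assert np.allclose(out.sum(axis=1), 1.0)


class TestPCA:
    def test_collinear_data_one_component(self):
        t = np.linspace(0, 1, 50)
        X = np.c_[t, 2 * t]
        _, _, var = pca_transform(X, 1)
        total = np.var(X - X.mean(0), axis=0, ddof=1).sum()
        assert var[0] == pytest.approx(total, rel=1e-10)

    def test_full_round_trip_and_orthonormality(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 5))
        Z, W, var = pca_transform(X, 5)
        assert np.allclose(W.T @ W, np.eye(5), atol=1e-10)
        recon = Z @ W.T + X.mean(axis=0)
        assert np.allclose(recon, X, atol=1e-8)
        assert np.all(np.diff(var) <= 1e-12)
        assert var.sum() == pytest.approx(np.var(X, axis=0, ddof=1).sum())

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 4)) @ rng.standard_normal((4, 4))
        Z, W, var = pca_transform(X, 3)
        ref = sklearn.PCA(n_components=3).fit(X)
        assert np.allclose(var, ref.explained_variance_, rtol=1e-8)
        assert np.allclose(np.abs(W.T), np.abs(ref.components_), atol=1e-8)

    def test_rank_guard(self):
        X = np.c_[np.arange(5.0), np.arange(5.0)]
        with pytest.raises(ValueError):
            pca_transform(X, 2)


class TestChiSquare:
    def test_uniform_table_zero(self):
        assert chi_square_score([[10, 10], [10, 10]]) == 0.0

    def test_diagonal_table_hand_value(self):
        assert chi_square_score([[20, 0], [0, 20]]) == pytest.approx(40.0)

    def test_matches_scipy_on_random_tables(self):
        from scipy.stats import chi2_contingency
        rng = np.random.default_rng(2)
        for _ in range(10):
            tab = rng.integers(1, 50, size=(3, 4))
            stat = chi2_contingency(tab, correction=False).statistic
            assert chi_square_score(tab) == pytest.approx(stat, rel=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_score([[0, 0], [5, 5]])


class TestRFE:
    def test_identity_selection(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 4))
        y = rng.integers(0, 2, 30)
        assert rfe_select(X, y, 4).tolist() == [0, 1, 2, 3]

    def test_recovers_single_signal_feature(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 200)
            X = rng.standard_normal((200, 5))
            X[:, 0] += (y - 0.5) * 3.0  # only feature 0 separates classes
            hits += rfe_select(X, y, 1).tolist() == [0]
        assert hits >= 95

    def test_output_sorted_unique(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 6))
        y = rng.integers(0, 2, 50)
        idx = rfe_select(X, y, 3)
        assert sorted(set(idx.tolist())) == idx.tolist()


def test_derive_bmi_values():
    assert derive_bmi(70, 1.75) == pytest.approx(22.857, abs=1e-3)
    assert derive_bmi(100, 2.0) == 25.0
    assert derive_bmi(0, 1.8) == 0.0
    with pytest.raises(ValueError):
        derive_bmi(70, 0.0)


class TestAugment:
    def test_output_count(self):
        imgs = [np.ones((8, 8)), np.zeros((8, 8))]
        out = augment_images(imgs, ["rotate", "flip", "noise"], seed=0)
        assert len(out) == 2 * (1 + 3)

    def test_flip_involution_and_rotation_cycle(self):
        img = np.arange(16.0).reshape(4, 4)
        assert np.array_equal(np.fliplr(np.fliplr(img)), img)
        assert np.array_equal(np.rot90(img, 4), img)

    def test_zero_noise_is_identity(self):
        img = np.arange(9.0).reshape(3, 3)
        out = augment_images([img], ["noise"], seed=0, noise_sd=0.0)
        assert np.array_equal(out[1], img)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            augment_images([np.zeros((0, 0))], ["flip"], seed=0)


class TestSplit:
    def test_balanced_1000_gives_700_150_150(self):
        ds = synthdata.make_tabular(SynthSpec(n_samples=1000, class_prior=0.5, seed=20))
        # force exact balance by construction
        y = np.r_[np.zeros(500, int), np.ones(500, int)]
        ds = LabeledDataset(ds.frame, y, ds.schema)
        b = stratified_split(ds, seed=1)
        assert (len(b.train), len(b.valid), len(b.test)) == (700, 150, 150)
        for part in (b.train, b.valid, b.test):
            assert part.y.sum() * 2 == len(part)  # 350/75/75 per class

    def test_partition_disjoint_exhaustive(self):
        ds = synthdata.make_tabular(SynthSpec(n_samples=237, seed=21))
        b = stratified_split(ds, seed=2)
        assert sorted(b.permutation.tolist()) == list(range(237))

    def test_seed_determinism(self):
        ds = synthdata.make_tabular(SynthSpec(n_samples=100, seed=22))
        a = stratified_split(ds, seed=3)
        b = stratified_split(ds, seed=3)
        assert np.array_equal(a.permutation, b.permutation)

    def test_small_class_rejected(self):
        ds = _tiny([1.0, 2.0, 3.0, 4.0], y=np.array([0, 0, 0, 1]))
        with pytest.raises(ValueError):
            stratified_split(ds)


class TestPipeline:
    def test_design_matrix_in_unit_interval_and_no_missing(self):
        spec = SynthSpec(n_samples=400, n_timeseries=1, missing_rate=0.05,
                         outlier_rate=0.01, seed=23)
        s = Preprocessor(seed=23).run(synthdata.make_dataset(spec))
        for X in (s.X_train, s.X_valid, s.X_test):
            assert np.isfinite(X).all()
            assert X.min() >= 0.0 and X.max() <= 1.0

    def test_transform_matches_run_on_test_part(self):
        spec = SynthSpec(n_samples=300, seed=24)
        data = synthdata.make_dataset(spec)
        pre = Preprocessor(seed=24)
        s = pre.run(data)
        from hdbncaen.preprocess import stratified_split as split
        b = split(data, seed=24)
        X, y, _ = pre.transform(b.test)
        assert np.allclose(X, s.X_test)
        assert np.array_equal(y, s.y_test)
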