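"""Split contracts and leakage-safe preprocessing transforms."""

import json

import numpy as np
import pandas as pd
import pytest

from darpipe.preprocess import (FittedTransformer, TransformSpec, fit_transform,
                                split)


def _table(n=100, seed=0, n_animals=10):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "animal_id": [f"A{i % n_animals}" for i in range(n)],
        "label": rng.choice(["a", "b", "c"], size=n, p=[0.6, 0.3, 0.1]),
        "f1": rng.normal(0, 1, n),
        "f2": rng.normal(5, 2, n),
    })


class TestSplit:
    def test_sizes_64_16_20(self):
        idx = split(_table(100), (0.64, 0.16, 0.20), seed=11)
        assert (len(idx.train), len(idx.validation), len(idx.test)) == (64, 16, 20)

    def test_disjoint_and_exhaustive(self):
        idx = split(_table(137), seed=1)
        allidx = np.concatenate([idx.train, idx.validation, idx.test])
        assert len(allidx) == 137 and len(set(allidx)) == 137

    def test_reproducible_under_seed(self):
        a = split(_table(100), seed=7)
        b = split(_table(100), seed=7)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.test, b.test)

    def test_stratification_keeps_class_shares(self):
        t = _table(500, seed=2)
        idx = split(t, seed=3)
        overall = t["label"].value_counts(normalize=True)
        train_share = t.iloc[idx.train]["label"].value_counts(normalize=True)
        assert (train_share - overall).abs().max() < 0.05

    def test_grouped_mode_no_animal_spans_partitions(self):
        t = _table(200, seed=4, n_animals=10)
        idx = split(t, seed=5, mode="grouped")
        parts = {}
        for name, ix in (("tr", idx.train), ("va", idx.validation),
                         ("te", idx.test)):
            for a in t.iloc[ix]["animal_id"]:
                assert parts.setdefault(a, name) == name

    def test_grouped_mode_one_animal_rejected(self):
        t = _table(50, n_animals=1)
        with pytest.raises(ValueError):
            split(t, mode="grouped")

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split(_table(10), (0.5, 0.4, 0.2))


class TestTransforms:
    def test_impute_uses_training_median(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0, np.nan]})
        test = pd.DataFrame({"f": [np.nan, np.nan]})
        tf = fit_transform(TransformSpec((("impute", {}),)), train, ["f"])
        out = tf.apply(test)
        assert (out["f"] == 2.0).all()

    def test_scale_center_train_stats(self):
        train = pd.DataFrame({"f": np.random.default_rng(0).normal(3, 2, 200)})
        tf = fit_transform(TransformSpec((("scale_center", {}),)), train, ["f"])
        out = tf.apply(train)
        assert out["f"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["f"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_scale_center_matches_sklearn(self):
        from sklearn.preprocessing import StandardScaler
        rng = np.random.default_rng(1)
        train = pd.DataFrame({"f": rng.normal(3, 2, 100), "g": rng.uniform(0, 9, 100)})
        test = pd.DataFrame({"f": rng.normal(0, 1, 30), "g": rng.uniform(0, 9, 30)})
        tf = fit_transform(TransformSpec((("scale_center", {}),)), train)
        ours = tf.apply(test).to_numpy()
        theirs = StandardScaler().fit(train).transform(test)
        assert np.allclose(ours, theirs)

    def test_zero_variance_centered_not_scaled(self):
        train = pd.DataFrame({"f": [4.0] * 10 + [5.0]})
        # 2 distinct values would be an indicator candidate; use 3
        train = pd.DataFrame({"f": [4.0] * 10, "g": [1.0, 2.0, 3.0] * 3 + [2.0]})
        tf = fit_transform(TransformSpec((("scale_center", {}),)), train)
        out = tf.apply(train)
        assert (out["f"] == 0.0).all()

    def test_one_hot_expands_sparse_feature(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0]})
        tf = fit_transform(
            TransformSpec((("threshold_one_hot", {"threshold": 5}),)), train)
        out = tf.apply(train)
        assert sorted(out.columns) == ["f=1", "f=2", "f=3"]
        assert out.sum(axis=1).eq(1.0).all()

    def test_one_hot_leaves_dense_feature_numeric(self):
        train = pd.DataFrame({"f": np.arange(31, dtype=float)})
        tf = fit_transform(
            TransformSpec((("threshold_one_hot", {"threshold": 30}),)), train)
        out = tf.apply(train)
        assert list(out.columns) == ["f"]

    def test_one_hot_unseen_value_all_zero(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 1.0]})
        test = pd.DataFrame({"f": [9.0]})
        tf = fit_transform(
            TransformSpec((("threshold_one_hot", {"threshold": 5}),)), train)
        out = tf.apply(test)
        assert out.iloc[0].sum() == 0.0

    def test_quantile_uniform_maps_to_unit_interval(self):
        rng = np.random.default_rng(2)
        train = pd.DataFrame({"f": rng.lognormal(0, 2, 500)})
        tf = fit_transform(TransformSpec((("quantile_uniform", {}),)), train)
        out = tf.apply(train)["f"]
        assert out.min() >= 0.0 and out.max() <= 1.0
        # extreme unseen value clamps to 1
        assert tf.apply(pd.DataFrame({"f": [1e12]}))["f"].iloc[0] == 1.0

    def test_pca_keeps_declared_variance(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1, (300, 2))
        train = pd.DataFrame(
            {"a": z[:, 0], "b": z[:, 0] + 0.01 * rng.normal(size=300),
             "c": z[:, 1]})
        tf = fit_transform(TransformSpec((("pca", {"variance_kept": 0.95}),)), train)
        out = tf.apply(train)
        assert out.shape[1] == 2  # third dimension is ~noise

    def test_pca_matches_sklearn_dimensionality(self):
        from sklearn.decomposition import PCA as SkPCA
        rng = np.random.default_rng(4)
        train = pd.DataFrame(rng.normal(size=(120, 6)),
                             columns=list("abcdef"))
        tf = fit_transform(TransformSpec((("pca", {"variance_kept": 0.9}),)), train)
        ours = tf.apply(train)
        theirs = SkPCA(n_components=0.9).fit_transform(train)
        assert ours.shape == theirs.shape
        assert np.allclose(np.abs(ours.to_numpy()), np.abs(theirs), atol=1e-6)

    def test_json_round_trip(self):
        rng = np.random.default_rng(5)
        train = pd.DataFrame({"f": rng.normal(size=50),
                              "g": rng.integers(0, 3, 50).astype(float)})
        test = pd.DataFrame({"f": rng.normal(size=20),
                             "g": rng.integers(0, 4, 20).astype(float)})
        spec = TransformSpec((("impute", {}),
                              ("threshold_one_hot", {"threshold": 5}),
                              ("scale_center", {}),
                              ("pca", {"variance_kept": 0.95})))
        tf = fit_transform(spec, train)
        back = FittedTransformer.from_json(tf.to_json())
        assert np.allclose(tf.apply(test).to_numpy(), back.apply(test).to_numpy())

    def test_missing_column_rejected(self):
        tf = fit_transform(TransformSpec((("impute", {}),)),
                           pd.DataFrame({"f": [1.0]}), ["f"])
        with pytest.raises(ValueError, match="f"):
            tf.apply(pd.DataFrame({"g": [1.0]}))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            TransformSpec((("threshold_one_hot", {"threshold": 1}),))
        with pytest.raises(ValueError):
            TransformSpec((("pca", {"variance_kept": 1.5}),))


class TestLeakage:
    def test_fitted_statistics_ignore_test_rows(self):
        """Sentinel: shift the test distribution; fitted stats must match the
        train-only recomputation and differ from any train+test recomputation."""
        rng = np.random.default_rng(6)
        train = pd.DataFrame({"f": rng.normal(0, 1, 200)})
        test = pd.DataFrame({"f": rng.normal(50, 1, 100)})  # strongly shifted
        tf = fit_transform(TransformSpec((("scale_center", {}),)), train)
        fitted_mean = tf.steps[0].means_["f"]
        assert fitted_mean == pytest.approx(train["f"].mean())
        combined_mean = pd.concat([train, test])["f"].mean()
        assert abs(fitted_mean - combined_mean) > 1.0
        # applying to test must use the train statistics
        out = tf.apply(test)["f"]
        assert out.mean() == pytest.approx(
            (test["f"].mean() - fitted_mean) / tf.steps[0].sds_["f"])
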