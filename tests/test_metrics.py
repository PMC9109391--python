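"""Confusion-matrix metrics against brute-force and library oracles."""

import numpy as np
import pandas as pd
import pytest

from darpipe.metrics import (ABLATION_COMBOS, ConfusionMatrix, ablation_run,
                             ablation_table, aggregate_metrics, confusion,
                             evaluate, per_class_metrics)
from darpipe.reference import REFERENCE_CONFUSION
from darpipe.simulate import CLASSES


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        labels = ["Dead"] * 6 + ["Local"] * 4
        cm = confusion(labels, labels)
        assert np.trace(cm.counts) == 10
        assert cm.counts.sum() == 10

    def test_single_pair(self):
        cm = confusion(["Dead"], ["Dead"])
        i = CLASSES.index("Dead")
        assert cm.counts[i, i] == 1 and cm.total == 1

    def test_reference_brooding_row_from_label_pairs(self):
        """Rebuild the published Brooding row from its label sequence."""
        actual = ["Brooding"] * 21
        predicted = (["Brooding"] * 8 + ["Local"] * 2 + ["Molt-like"] * 11)
        cm = confusion(actual, predicted)
        b = CLASSES.index("Brooding")
        assert cm.counts[b].tolist() == [8, 0, 2, 0, 11, 0, 0, 0]
        assert cm.counts[b].tolist() == REFERENCE_CONFUSION.counts[b].tolist()

    def test_unknown_label_named(self):
        with pytest.raises(ValueError, match="Flying"):
            confusion(["Flying"], ["Dead"])
        with pytest.raises(ValueError, match="Flying"):
            confusion(["Dead"], ["Flying"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(["Dead"], [])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(("a", "b"), np.array([[1, -1], [0, 0]]))


class TestPerClass:
    def test_reference_per_class_values(self):
        pc = per_class_metrics(REFERENCE_CONFUSION)
        assert pc.loc["Brooding", "recall"] == pytest.approx(8 / 21)
        assert pc.loc["Brooding", "precision"] == pytest.approx(1.0)
        assert round(pc.loc["Brooding", "f1"], 3) == 0.552
        assert pc.loc["Molting", "precision"] == pytest.approx(73 / 76)
        assert pc.loc["Molting", "recall"] == pytest.approx(73 / 87)
        assert round(pc.loc["Molting", "f1"], 3) == 0.896

    def test_empty_class_scored_zero_with_warning(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[1, 1] = 5
        with pytest.warns(UserWarning, match="no support"):
            pc = per_class_metrics(ConfusionMatrix(CLASSES, counts))
        assert pc.loc["Brooding", ["precision", "recall", "f1"]].eq(0).all()


def _brute_force_metrics(actual, predicted, classes):
    """Independent recount over raw label pairs (no matrix algebra)."""
    out = {}
    for c in classes:
        tp = sum(1 for a, p in zip(actual, predicted) if a == c and p == c)
        fp = sum(1 for a, p in zip(actual, predicted) if a != c and p == c)
        fn = sum(1 for a, p in zip(actual, predicted) if a == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[c] = (prec, rec, f1, tp + fn)
    return out


class TestAggregates:
    def test_reference_aggregates(self):
        rep = aggregate_metrics(REFERENCE_CONFUSION)
        assert round(rep.micro_accuracy, 3) == 0.952
        assert round(rep.macro_f1, 3) == 0.899
        assert round(rep.weighted_f1, 3) == 0.950
        assert round(rep.macro_precision, 3) == 0.963
        assert round(rep.macro_recall, 3) == 0.871

    def test_one_class_matrix(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[2, 2] = 7
        with pytest.warns(UserWarning):
            rep = aggregate_metrics(ConfusionMatrix(CLASSES, counts))
        assert rep.weighted_f1 == 1.0
        assert rep.macro_f1 == pytest.approx(1 / 8)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            aggregate_metrics(ConfusionMatrix(CLASSES, np.zeros((8, 8), int)))

    def test_fuzz_against_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(2, 9))
            classes = CLASSES[:k]
            actual = rng.choice(classes, size=n)
            predicted = rng.choice(classes, size=n)
            cm = confusion(actual, predicted, classes)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pc = per_class_metrics(cm)
                rep = aggregate_metrics(cm)
            oracle = _brute_force_metrics(actual, predicted, classes)
            for c in classes:
                prec, rec, f1, support = oracle[c]
                assert pc.loc[c, "precision"] == pytest.approx(prec)
                assert pc.loc[c, "recall"] == pytest.approx(rec)
                assert pc.loc[c, "f1"] == pytest.approx(f1)
                assert pc.loc[c, "support"] == support
            # identity: support-weighted recall == micro accuracy
            assert rep.weighted_recall == pytest.approx(rep.micro_accuracy)
            acc_oracle = sum(a == p for a, p in zip(actual, predicted)) / n
            assert rep.micro_accuracy == pytest.approx(acc_oracle)

    def test_matches_sklearn(self):
        from sklearn.metrics import f1_score
        rng = np.random.default_rng(9)
        actual = rng.choice(CLASSES, size=300)
        predicted = rng.choice(CLASSES, size=300)
        rep = evaluate(actual, predicted)
        assert rep.macro_f1 == pytest.approx(
            f1_score(actual, predicted, average="macro", zero_division=0))
        assert rep.weighted_f1 == pytest.approx(
            f1_score(actual, predicted, average="weighted", zero_division=0))


class TestAblation:
    def test_combo_without_movement_rejected(self, tiny_features):
        from darpipe.models import make_candidates
        from darpipe.preprocess import split
        idx = split(tiny_features, seed=0)
        with pytest.raises(ValueError, match="movement"):
            ablation_run(tiny_features, {"H": ("habitat",)},
                         make_candidates()[0], {}, idx)

    def test_single_combo_single_report(self, tiny_features):
        from darpipe.models import make_candidates
        from darpipe.preprocess import split
        idx = split(tiny_features, seed=0)
        params = dict(max_depth=3, learning_rate=0.2, n_estimators=60,
                      subsample=0.9, colsample_bytree=0.9,
                      reg_alpha=1e-3, reg_lambda=1.0)
        reports = ablation_run(tiny_features, ["MT"], make_candidates()[0],
                               params, idx, seed=0)
        assert list(reports) == ["MT"]
        table = ablation_table(reports)
        assert "Weighted-F1" in table.index

    def test_constant_raster_adds_nothing(self, tiny_pop):
        """With an uninformative (constant) habitat raster, MT+habitat
        performs like MT alone."""
        from darpipe.features import featurize_days
        from darpipe.landscape import WaterIndexGrid
        from darpipe.models import make_candidates
        from darpipe.preprocess import split
        flat = WaterIndexGrid(-30000, -30000, 500,
                              np.full((120, 120), 0.2))
        tab = featurize_days(tiny_pop.labeled_days, flat,
                             ("movement_timing", "habitat"))
        idx = split(tab, seed=1)
        params = dict(max_depth=4, learning_rate=0.2, n_estimators=80,
                      subsample=0.9, colsample_bytree=0.9,
                      reg_alpha=1e-3, reg_lambda=1.0)
        reports = ablation_run(tab, ["MT+habitat", "MT"],
                               make_candidates()[0], params, idx, seed=0)
        diff = abs(reports["MT+habitat"].weighted_f1 - reports["MT"].weighted_f1)
        assert diff < 0.05
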