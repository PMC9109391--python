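"""Feature catalogue contracts: counts, geometry oracles, invariances."""

import datetime

import numpy as np
import pandas as pd
import pytest

from darpipe.features import (FEATURE_NAMES, FEATURE_SCHEMA, FEATURE_SET_OF,
                              compute_features, featurize_days,
                              habitat_features, history_features,
                              mean_center, movement_timing_features)
from darpipe.landscape import WaterIndexGrid
from darpipe.tracking import DayTrack

DATE = datetime.date(2019, 4, 1)


def _track(xy, date=DATE, animal="a1"):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    ts = pd.date_range("2019-04-01T08:00:00Z", periods=n, freq="h")
    # lon/lat near the reference point; only used for photoperiod
    fixes = pd.DataFrame({"timestamp": ts,
                          "lon": -121.8 + xy[:, 0] / 111e3,
                          "lat": 39.3 + xy[:, 1] / 111e3,
                          "x": xy[:, 0], "y": xy[:, 1]})
    return DayTrack(animal, date, 60, fixes)


def _flags(n=24, n_day=12):
    return np.array([True] * n_day + [False] * (n - n_day))


class TestSchema:
    def test_set_counts(self):
        counts = FEATURE_SCHEMA["set"].value_counts()
        assert counts["movement_timing"] == 40
        assert counts["habitat"] == 8
        assert counts["history"] == 20
        assert len(FEATURE_NAMES) == 68

    def test_names_stable_and_unique(self):
        assert len(set(FEATURE_NAMES)) == 68
        assert FEATURE_NAMES[0] == "step_mean"


class TestMeanCenter:
    def test_centroid_at_origin(self, rng):
        t = _track(rng.normal(0, 500, (24, 2)) + [5000, -3000])
        xy, _ = mean_center(t)
        assert np.allclose(xy.mean(axis=0), 0, atol=1e-9)

    def test_translation_invariance_of_all_features(self, rng):
        base = rng.normal(0, 400, (24, 2))
        flags = _flags()
        f0 = movement_timing_features(mean_center(_track(base))[0], flags)
        f1 = movement_timing_features(
            mean_center(_track(base + [10_000.0, 0.0]))[0], flags)
        for name in f0:
            assert f0[name] == pytest.approx(f1[name], abs=1e-6), name

    def test_history_invariant_when_context_shifted_jointly(self, rng):
        base = rng.normal(0, 400, (24, 2))
        prior = rng.normal(0, 400, (24, 2)) + [800, 0]
        shift = np.array([25_000.0, -4_000.0])
        out = []
        for dx in (0.0, 1.0):
            t = _track(base + dx * shift)
            p = _track(prior + dx * shift, date=DATE - datetime.timedelta(days=1))
            xy, (pxy,) = mean_center(t, [p])
            out.append(history_features(xy, {"lag1": pxy}))
        for name in out[0]:
            a, b = out[0][name], out[1][name]
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert a == pytest.approx(b, abs=1e-6), name


class TestMovementTiming:
    def test_stationary_track_zeroes(self):
        feats = movement_timing_features(np.zeros((24, 2)), _flags())
        for name in ("total_path", "net_displacement", "hull_area", "step_max",
                     "radius_gyration", "max_displacement", "straightness"):
            assert feats[name] == 0.0

    def test_square_kilometre_path(self):
        # 1 km square, corners visited sequentially, 6 fixes per corner
        corners = [(0, 0), (1000, 0), (1000, 1000), (0, 1000)]
        xy = np.array([c for c in corners for _ in range(6)], dtype=float)
        feats = movement_timing_features(xy, _flags())
        assert feats["total_path"] == pytest.approx(3000.0)
        assert feats["net_displacement"] == pytest.approx(1000.0)

    def test_collinear_track_straightness_one(self):
        xy = np.column_stack([100.0 * np.arange(24), np.zeros(24)])
        feats = movement_timing_features(xy, _flags())
        assert feats["total_path"] == pytest.approx(2300.0)
        assert feats["net_displacement"] == pytest.approx(2300.0)
        assert feats["straightness"] == pytest.approx(1.0)
        assert feats["mean_cos_turn"] == pytest.approx(1.0)

    def test_incomplete_day_rejected(self):
        with pytest.raises(ValueError, match="24"):
            movement_timing_features(np.zeros((23, 2)), _flags(23, 12))

    def test_count_is_forty_and_finite(self, rng):
        feats = movement_timing_features(rng.normal(0, 300, (24, 2)), _flags())
        assert len(feats) == 40
        assert all(np.isfinite(v) for v in feats.values())


def _uniform_grid(value, size=5000.0, cell=100.0):
    n = int(size / cell)
    return WaterIndexGrid(-size / 2, -size / 2, cell,
                          np.full((n, n), value))


class TestHabitat:
    def test_uniform_raster(self, rng):
        xy = rng.normal(0, 300, (24, 2))
        feats = habitat_features(xy, _uniform_grid(0.5), _flags())
        assert feats["hab_mean"] == pytest.approx(0.5)
        assert feats["hab_min"] == pytest.approx(0.5)
        assert feats["hab_max"] == pytest.approx(0.5)
        assert feats["hab_sd"] == pytest.approx(0.0)
        assert feats["water_fraction"] == pytest.approx(1.0)
        assert len(feats) == 8

    def test_all_land(self, rng):
        xy = rng.normal(0, 300, (24, 2))
        feats = habitat_features(xy, _uniform_grid(-0.2), _flags())
        assert feats["water_fraction"] == 0.0

    def test_mixed_values(self):
        # half the fixes on a 0.4 water cell, half on a -0.4 land cell
        grid = _uniform_grid(-0.4)
        grid.values[:, grid.values.shape[1] // 2:] = 0.4
        xy = np.array([[-1000.0, 0.0]] * 12 + [[1000.0, 0.0]] * 12)
        feats = habitat_features(xy, grid, _flags())
        assert feats["hab_mean"] == pytest.approx(0.0)
        assert feats["water_fraction"] == pytest.approx(0.5)

    def test_out_of_extent_fixes_yield_nan(self):
        xy = np.full((24, 2), 1e7)
        feats = habitat_features(xy, _uniform_grid(0.5), _flags())
        assert np.isnan(feats["hab_mean"])


class TestHistory:
    def test_identical_window(self, rng):
        xy = rng.normal(0, 300, (24, 2))
        feats = history_features(xy, {"lag1": xy.copy()})
        assert feats["hist_lag1_centroid_dist"] == pytest.approx(0.0, abs=1e-9)
        assert feats["hist_lag1_overlap"] == 1.0
        assert feats["hist_lag1_rog_ratio"] == pytest.approx(1.0)
        assert feats["hist_lag1_nn_dist"] == pytest.approx(0.0, abs=1e-9)

    def test_distant_window(self, rng):
        xy = rng.normal(0, 100, (24, 2))
        far = rng.normal(0, 100, (24, 2)) + [10_000.0, 0.0]
        far -= xy.mean(axis=0)
        feats = history_features(xy - xy.mean(axis=0), {"lag1": far})
        assert feats["hist_lag1_centroid_dist"] == pytest.approx(10_000.0, rel=0.05)
        assert feats["hist_lag1_overlap"] == 0.0

    def test_stationary_bird_fixed_point(self):
        xy = np.zeros((24, 2))
        prior = {w: np.zeros((24, 2)) for w in
                 ("lag1", "lag2_3", "lag5_7", "lag8_10", "lag12_15")}
        feats = history_features(xy, prior)
        for name, v in feats.items():
            if name.endswith(("centroid_dist", "nn_dist")):
                assert v == 0.0
            elif name.endswith("overlap"):
                assert v == 1.0
            else:  # rog ratios
                assert v == pytest.approx(1.0)
        assert len(feats) == 20

    def test_missing_window_is_nan(self, rng):
        feats = history_features(rng.normal(0, 100, (24, 2)), {})
        assert all(np.isnan(v) for v in feats.values())


class TestFeaturizeDays:
    def test_table_shape_and_sets(self, tiny_features):
        feat_cols = [c for c in tiny_features.columns if c in FEATURE_SET_OF]
        assert len(feat_cols) == 68
        assert set(tiny_features.columns) - set(feat_cols) == {
            "animal_id", "date", "label"}

    def test_dead_moves_less_than_migration(self):
        from darpipe.simulate import default_regimes, simulate_day
        regs = default_regimes()
        rng = np.random.default_rng(7)
        paths = {}
        for cls in ("Dead", "Migration"):
            tracks = [simulate_day(cls, regs[cls], (0, 0), DATE, 60, rng)
                      for _ in range(20)]
            paths[cls] = [
                movement_timing_features(mean_center(t)[0], _flags())["total_path"]
                for t in tracks]
        assert max(paths["Dead"]) < min(paths["Migration"])

    def test_habitat_requires_raster(self, tiny_pop):
        with pytest.raises(ValueError, match="raster"):
            compute_features(tiny_pop.day_tracks[0], grid=None,
                             feature_sets=("movement_timing", "habitat"))
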