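"""Feature engineering for daily activity routines.

For every animal-day, 68 named features are computed in three sets:

* **movement & timing** (40): geometry and timing of the target day's 24
  fixes only — step-length statistics, path length, displacements, radius of
  gyration, convex-hull area, straightness, turning-angle persistence,
  sedentariness, cluster counts — for all fixes and for the daytime and
  nighttime subsets, plus day/night contrast ratios.
* **habitat** (8): summaries of the water index sampled at fix locations
  (mean/sd/min/max, photoperiod means, fraction of fixes on water, index at
  the most-used cluster).
* **history** (20): the target day's geometry relative to the same animal's
  fixes 1, 2-3, 5-7, 8-10 and 12-15 days earlier — 4 metrics (centroid
  distance, overlap with the window's radius, radius-of-gyration ratio,
  mean nearest-neighbour distance) x 5 lag windows.  Windows without data
  yield NaN (imputed downstream).

All features are computed after *mean-centring anonymisation*: each target
day's coordinates (and, jointly, its history context) are translated so the
target-day centroid is the origin.  Every feature is therefore invariant to
translation of the raw track; features are also rotation-invariant except the
photoperiod-related ones (rotation never enters: no bearing features are
used, but day/night splits depend on geography through solar geometry).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from collections import OrderedDict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from . import solar
from .landscape import WaterIndexGrid
from .tracking import DayTrack, LabeledDay

#: Steps shorter than this (m) count as "sedentary".
SEDENTARY_STEP_M = 50.0

#: Greedy cluster radius (m) for distinct-area counts.
CLUSTER_RADIUS_M = 500.0

#: Water/land threshold on the water index (MNDWI convention).
WATER_THRESHOLD = 0.0

#: History lag windows: (name, first lag, last lag) in days before target.
HISTORY_WINDOWS = (
    ("lag1", 1, 1),
    ("lag2_3", 2, 3),
    ("lag5_7", 5, 7),
    ("lag8_10", 8, 10),
    ("lag12_15", 12, 15),
)

_SUBSET_FEATURES = (
    "step_mean", "step_median", "step_max", "step_sd", "path_length",
    "net_displacement", "radius_gyration", "hull_area", "prop_sedentary",
    "mean_cos_turn",
)
_HISTORY_METRICS = ("centroid_dist", "overlap", "rog_ratio", "nn_dist")


def feature_schema() -> pd.DataFrame:
    """The stable feature catalogue: name, set tag, units, in fixed order."""
    rows: list[tuple[str, str, str]] = []
    mt = "movement_timing"
    for name, unit in [
        ("step_mean", "m"), ("step_median", "m"), ("step_max", "m"), ("step_sd", "m"),
        ("total_path", "m"), ("net_displacement", "m"), ("max_displacement", "m"),
        ("radius_gyration", "m"), ("hull_area", "m2"), ("straightness", "1"),
        ("mean_cos_turn", "1"), ("prop_sedentary", "1"), ("hour_max_step", "h"),
        ("n_clusters_500m", "count"), ("longest_stationary_run", "count"),
        ("first_fix_centroid_dist", "m"), ("last_fix_centroid_dist", "m"),
    ]:
        rows.append((name, mt, unit))
    for sub in ("day", "night"):
        for name in _SUBSET_FEATURES:
            unit = {"prop_sedentary": "1", "mean_cos_turn": "1",
                    "hull_area": "m2"}.get(name, "m")
            rows.append((f"{sub}_{name}", mt, unit))
    rows += [("day_night_path_ratio", mt, "1"),
             ("day_night_dispersion_ratio", mt, "1"),
             ("n_day_fixes", mt, "count")]
    for name in ("hab_mean", "hab_sd", "hab_min", "hab_max",
                 "hab_day_mean", "hab_night_mean", "water_fraction",
                 "hab_main_cluster"):
        rows.append((name, "habitat", "index"))
    for wname, _, _ in HISTORY_WINDOWS:
        for metric in _HISTORY_METRICS:
            unit = {"centroid_dist": "m", "nn_dist": "m"}.get(metric, "1")
            rows.append((f"hist_{wname}_{metric}", "history", unit))
    schema = pd.DataFrame(rows, columns=["name", "set", "unit"])
    counts = schema["set"].value_counts()
    assert counts["movement_timing"] == 40 and counts["habitat"] == 8 \
        and counts["history"] == 20
    return schema


FEATURE_SCHEMA = feature_schema()
FEATURE_NAMES = tuple(FEATURE_SCHEMA["name"])
FEATURE_SET_OF = dict(zip(FEATURE_SCHEMA["name"], FEATURE_SCHEMA["set"]))


def write_schema_json(path) -> None:
    FEATURE_SCHEMA.to_json(path, orient="records", indent=2)


# ---------------------------------------------------------------------------
# Anonymisation and photoperiod
# ---------------------------------------------------------------------------

def mean_center(
    day_track: DayTrack, context_tracks: Sequence[DayTrack] = ()
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Translate target-day (and jointly its context) so the target centroid
    is the origin.  Returns centred (n, 2) coordinate arrays."""
    xy = day_track.fixes[["x", "y"]].to_numpy(dtype=float)
    centroid = xy.mean(axis=0)
    ctx = [t.fixes[["x", "y"]].to_numpy(dtype=float) - centroid for t in context_tracks]
    return xy - centroid, ctx


def split_photoperiod(day_track: DayTrack) -> np.ndarray:
    """Per-fix day/night flags from solar elevation at the track centroid."""
    lat = float(day_track.fixes["lat"].mean())
    lon = float(day_track.fixes["lon"].mean())
    return solar.day_flags(lat, lon, day_track.fixes["timestamp"])


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _step_lengths(xy: np.ndarray) -> np.ndarray:
    return np.hypot(*np.diff(xy, axis=0).T) if len(xy) > 1 else np.zeros(0)


def _radius_of_gyration(xy: np.ndarray) -> float:
    if len(xy) == 0:
        return 0.0
    c = xy.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((xy - c) ** 2, axis=1))))


def _hull_area(xy: np.ndarray) -> float:
    if len(xy) < 3:
        return 0.0
    return float(MultiPoint([tuple(p) for p in xy]).convex_hull.area)


def _mean_cos_turn(xy: np.ndarray) -> float:
    d = np.diff(xy, axis=0)
    lens = np.hypot(d[:, 0], d[:, 1]) if len(d) else np.zeros(0)
    keep = lens > 1e-9
    d = d[keep]
    if len(d) < 2:
        return 0.0
    u = d / np.hypot(d[:, 0], d[:, 1])[:, None]
    return float(np.mean(np.sum(u[:-1] * u[1:], axis=1)))


def _greedy_clusters(xy: np.ndarray, radius: float) -> np.ndarray:
    """Greedy distance clustering; returns per-fix cluster ids."""
    seeds: list[np.ndarray] = []
    ids = np.empty(len(xy), dtype=int)
    for i, p in enumerate(xy):
        if seeds:
            d = [float(np.hypot(*(p - s))) for s in seeds]
            j = int(np.argmin(d))
            if d[j] <= radius:
                ids[i] = j
                continue
        seeds.append(p)
        ids[i] = len(seeds) - 1
    return ids


def _subset_stats(xy: np.ndarray) -> dict[str, float]:
    steps = _step_lengths(xy)
    out = {
        "step_mean": float(steps.mean()) if steps.size else 0.0,
        "step_median": float(np.median(steps)) if steps.size else 0.0,
        "step_max": float(steps.max()) if steps.size else 0.0,
        "step_sd": float(steps.std()) if steps.size else 0.0,
        "path_length": float(steps.sum()),
        "net_displacement": float(np.hypot(*(xy[-1] - xy[0]))) if len(xy) else 0.0,
        "radius_gyration": _radius_of_gyration(xy),
        "hull_area": _hull_area(xy),
        "prop_sedentary": float((steps < SEDENTARY_STEP_M).mean()) if steps.size else 0.0,
        "mean_cos_turn": _mean_cos_turn(xy),
    }
    return out


# ---------------------------------------------------------------------------
# Feature-set computations
# ---------------------------------------------------------------------------

def movement_timing_features(xy: np.ndarray, day_flags: np.ndarray) -> OrderedDict:
    """The 40 movement & timing features from centred coordinates."""
    if len(xy) != 24:
        raise ValueError("movement/timing features require a complete 24-fix day")
    steps = _step_lengths(xy)
    centroid = xy.mean(axis=0)
    from_first = np.hypot(*(xy - xy[0]).T)
    sed = steps < SEDENTARY_STEP_M
    # longest run of consecutive sedentary steps
    longest = run = 0
    for s in sed:
        run = run + 1 if s else 0
        longest = max(longest, run)
    cluster_ids = _greedy_clusters(xy, CLUSTER_RADIUS_M)
    out: OrderedDict[str, float] = OrderedDict()
    out["step_mean"] = float(steps.mean())
    out["step_median"] = float(np.median(steps))
    out["step_max"] = float(steps.max())
    out["step_sd"] = float(steps.std())
    out["total_path"] = float(steps.sum())
    out["net_displacement"] = float(np.hypot(*(xy[-1] - xy[0])))
    out["max_displacement"] = float(from_first.max())
    out["radius_gyration"] = _radius_of_gyration(xy)
    out["hull_area"] = _hull_area(xy)
    out["straightness"] = (out["net_displacement"] / out["total_path"]
                           if out["total_path"] > 0 else 0.0)
    out["mean_cos_turn"] = _mean_cos_turn(xy)
    out["prop_sedentary"] = float(sed.mean())
    out["hour_max_step"] = float(int(np.argmax(steps)) + 1)
    out["n_clusters_500m"] = float(cluster_ids.max() + 1)
    out["longest_stationary_run"] = float(longest)
    out["first_fix_centroid_dist"] = float(np.hypot(*(xy[0] - centroid)))
    out["last_fix_centroid_dist"] = float(np.hypot(*(xy[-1] - centroid)))
    day_stats = _subset_stats(xy[day_flags])
    night_stats = _subset_stats(xy[~day_flags])
    for name in _SUBSET_FEATURES:
        out[f"day_{name}"] = day_stats[name]
    for name in _SUBSET_FEATURES:
        out[f"night_{name}"] = night_stats[name]
    dp, np_ = day_stats["path_length"], night_stats["path_length"]
    out["day_night_path_ratio"] = dp / (dp + np_) if (dp + np_) > 0 else 0.5
    dr, nr = day_stats["radius_gyration"], night_stats["radius_gyration"]
    out["day_night_dispersion_ratio"] = dr / (dr + nr) if (dr + nr) > 0 else 0.5
    out["n_day_fixes"] = float(day_flags.sum())
    return out


def habitat_features(xy_raw: np.ndarray, grid: WaterIndexGrid,
                     day_flags: np.ndarray) -> OrderedDict:
    """The 8 habitat features: water-index summaries at *raw* fix locations.

    The grid lives in raw (un-anonymised) coordinates, so sampling uses the
    original positions; the resulting values are translation-invariant
    summaries of attributes, not coordinates.  Fixes outside the grid extent
    are excluded from the summaries (all-outside days yield NaN).
    """
    vals = grid.sample(xy_raw[:, 0], xy_raw[:, 1])
    ok = ~np.isnan(vals)
    out: OrderedDict[str, float] = OrderedDict()
    if ok.any():
        v = vals[ok]
        out["hab_mean"] = float(v.mean())
        out["hab_sd"] = float(v.std())
        out["hab_min"] = float(v.min())
        out["hab_max"] = float(v.max())
        dsel = ok & day_flags
        nsel = ok & ~day_flags
        out["hab_day_mean"] = float(vals[dsel].mean()) if dsel.any() else float(v.mean())
        out["hab_night_mean"] = float(vals[nsel].mean()) if nsel.any() else float(v.mean())
        out["water_fraction"] = float((v > WATER_THRESHOLD).mean())
        ids = _greedy_clusters(xy_raw, CLUSTER_RADIUS_M)
        main = np.bincount(ids).argmax()
        mvals = vals[(ids == main) & ok]
        out["hab_main_cluster"] = float(mvals.mean()) if mvals.size else float(v.mean())
    else:
        for name in ("hab_mean", "hab_sd", "hab_min", "hab_max", "hab_day_mean",
                     "hab_night_mean", "water_fraction", "hab_main_cluster"):
            out[name] = float("nan")
    return out


def history_features(
    target_xy: np.ndarray,
    prior: Mapping[str, np.ndarray],
) -> OrderedDict:
    """The 20 history features: target-day geometry vs 5 lag windows.

    ``prior`` maps window name -> pooled (m, 2) coordinates of that window's
    day-tracks, already centred jointly with the target day.  Empty/missing
    windows produce NaN for their 4 metrics.
    """
    eps = 1.0  # m; keeps ratios finite and =1 at the no-movement fixed point
    rog_t = _radius_of_gyration(target_xy)
    out: OrderedDict[str, float] = OrderedDict()
    for wname, _, _ in HISTORY_WINDOWS:
        w = prior.get(wname)
        if w is None or len(w) == 0:
            for metric in _HISTORY_METRICS:
                out[f"hist_{wname}_{metric}"] = float("nan")
            continue
        wc = w.mean(axis=0)
        tc = target_xy.mean(axis=0)
        out[f"hist_{wname}_centroid_dist"] = float(np.hypot(*(tc - wc)))
        # window radius = farthest window fix from the window centroid, so an
        # identical window yields overlap exactly 1
        radius = float(np.hypot(*(w - wc).T).max())
        dist_to_wc = np.hypot(*(target_xy - wc).T)
        out[f"hist_{wname}_overlap"] = float((dist_to_wc <= radius + 1e-9).mean())
        rog_w = _radius_of_gyration(w)
        out[f"hist_{wname}_rog_ratio"] = float((rog_t + eps) / (rog_w + eps))
        nn = cKDTree(w).query(target_xy, k=1)[0]
        out[f"hist_{wname}_nn_dist"] = float(np.mean(nn))
    return out


# ---------------------------------------------------------------------------
# Per-day orchestration
# ---------------------------------------------------------------------------

def compute_features(
    day_track: DayTrack,
    grid: WaterIndexGrid | None = None,
    prior_tracks: Sequence[DayTrack] = (),
    feature_sets: Sequence[str] = ("movement_timing", "habitat", "history"),
) -> OrderedDict:
    """All requested feature sets for one animal-day.

    ``prior_tracks`` are the same animal's earlier day-tracks; they are
    assigned to lag windows by calendar-day difference from the target date.
    """
    flags = split_photoperiod(day_track)
    xy_raw = day_track.fixes[["x", "y"]].to_numpy(dtype=float)
    by_window: dict[str, list[DayTrack]] = {w: [] for w, _, _ in HISTORY_WINDOWS}
    for t in prior_tracks:
        lag = (day_track.date - t.date).days
        for wname, lo, hi in HISTORY_WINDOWS:
            if lo <= lag <= hi:
                by_window[wname].append(t)
    ordered_ctx = [t for w, _, _ in HISTORY_WINDOWS for t in by_window[w]]
    xy, ctx = mean_center(day_track, ordered_ctx)
    prior_xy: dict[str, np.ndarray] = {}
    i = 0
    for wname, _, _ in HISTORY_WINDOWS:
        k = len(by_window[wname])
        prior_xy[wname] = (np.vstack(ctx[i:i + k]) if k else np.zeros((0, 2)))
        i += k
    out: OrderedDict[str, float] = OrderedDict()
    if "movement_timing" in feature_sets:
        out.update(movement_timing_features(xy, flags))
    if "habitat" in feature_sets:
        if grid is None:
            raise ValueError("habitat feature set requested but no raster given")
        out.update(habitat_features(xy_raw, grid, flags))
    if "history" in feature_sets:
        out.update(history_features(xy, prior_xy))
    return out


def featurize_days(
    days: Sequence[LabeledDay] | Sequence[DayTrack],
    grid: WaterIndexGrid | None = None,
    feature_sets: Sequence[str] = ("movement_timing", "habitat", "history"),
) -> pd.DataFrame:
    """Feature table for a collection of animal-days.

    One row per day-track with id columns ``animal_id``/``date`` (and
    ``label`` when the input is labelled), then the feature columns in schema
    order.  History windows draw on the other day-tracks of the same animal.
    """
    items: list[tuple[DayTrack, str | None]] = []
    for d in days:
        if isinstance(d, LabeledDay):
            items.append((d.day_track, d.label))
        else:
            items.append((d, None))
    by_animal: dict[str, list[DayTrack]] = {}
    for track, _ in items:
        by_animal.setdefault(track.animal_id, []).append(track)
    max_lag = max(hi for _, _, hi in HISTORY_WINDOWS)
    rows = []
    for track, label in items:
        prior = [t for t in by_animal[track.animal_id]
                 if 0 < (track.date - t.date).days <= max_lag]
        feats = compute_features(track, grid, prior, feature_sets)
        row = {"animal_id": track.animal_id, "date": track.date}
        if label is not None:
            row["label"] = label
        row.update(feats)
        rows.append(row)
    df = pd.DataFrame(rows)
    wanted = [n for n in FEATURE_NAMES if FEATURE_SET_OF[n] in feature_sets]
    id_cols = [c for c in ("animal_id", "date", "label") if c in df.columns]
    return df[id_cols + wanted]


def feature_columns(df: pd.DataFrame) -> list[str]:
    """The feature columns of a feature table (schema order)."""
    return [c for c in FEATURE_NAMES if c in df.columns]
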