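"""Tracking-data I/O and day-track assembly.

The classification unit throughout the package is one *animal-day*: a complete
set of regularly spaced GPS fixes spanning a single local calendar day
(24 fixes at hourly, 48 at half-hourly, 96 at quarter-hourly intervals).
This module reads raw fix tables, assembles complete day-tracks, excludes
defective days, subsets sub-hourly days into independent hourly day-tracks
("augmentation"), and projects geographic coordinates to local metric
coordinates for geometry.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mean Earth radius in metres (IUGG).
EARTH_RADIUS_M = 6_371_008.8

#: Supported fix intervals (minutes) and expected fixes per day.
FIXES_PER_DAY = {60: 24, 30: 48, 15: 96}

#: Study region is California's Central Valley; days are bounded at local
#: civil midnight in a fixed-offset zone (UTC-8, no DST) unless overridden.
DEFAULT_TIMEZONE = "Etc/GMT+8"

#: Tolerance (minutes) on the nominal fix schedule before a day is rejected.
SPACING_TOLERANCE_MIN = 5.0

REQUIRED_COLUMNS = ("animal_id", "timestamp", "lon", "lat")


class SchemaError(ValueError):
    """Input table does not have the expected columns."""


@dataclasses.dataclass
class DayTrack:
    """One animal-day of ordered, regularly spaced GPS fixes.

    ``fixes`` is a DataFrame with columns ``timestamp`` (tz-aware UTC),
    ``lon``, ``lat`` and, once projected, ``x``/``y`` in metres.
    ``offset_index`` records which sub-hourly phase an augmented hourly track
    came from (0 for native hourly data).
    """

    animal_id: str
    date: datetime.date
    interval_minutes: int
    fixes: pd.DataFrame
    offset_index: int = 0

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    def __post_init__(self) -> None:
        if self.interval_minutes not in FIXES_PER_DAY:
            raise ValueError(
                f"unsupported interval {self.interval_minutes} min; "
                f"expected one of {sorted(FIXES_PER_DAY)}"
            )


@dataclasses.dataclass
class LabeledDay:
    """A day-track with its life-history / movement-pattern label."""

    day_track: DayTrack
    label: str


def read_tracks(path, timezone: str = "UTC") -> pd.DataFrame:
    """Read a tracking CSV into a fix table.

    The CSV must have columns ``animal_id, timestamp, lon, lat`` with
    ISO-8601 UTC timestamps.  Returns a DataFrame sorted by
    ``(animal_id, timestamp)`` with exact duplicate rows dropped (and the
    number dropped logged).  ``timezone`` is attached as the frame attribute
    ``local_timezone`` for downstream day-boundary logic.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"tracking CSV missing required column(s): {missing}")
    try:
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        # fall back row by row so the offending line can be reported
        ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
        bad = np.flatnonzero(ts.isna().to_numpy())
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"unparseable timestamp at CSV line {bad[0] + 2}: "
                f"{df['timestamp'].iloc[bad[0]]!r}"
            )
    df = df.assign(timestamp=ts)
    if not df["lon"].between(-180, 180).all() or not df["lat"].between(-90, 90).all():
        raise ValueError("lon/lat outside WGS84 bounds")
    n0 = len(df)
    df = df.drop_duplicates(subset=["animal_id", "timestamp", "lon", "lat"])
    dropped = n0 - len(df)
    if dropped:
        logger.info("read_tracks: dropped %d exact duplicate rows", dropped)
    df = df.sort_values(["animal_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    df.attrs["local_timezone"] = timezone
    df.attrs["n_duplicates_dropped"] = dropped
    return df


def build_day_tracks(
    fixes: pd.DataFrame,
    interval_minutes: int,
    timezone: str | None = None,
) -> tuple[list[DayTrack], pd.DataFrame]:
    """Group fixes into complete day-tracks; exclude defective days.

    A day is kept only if it has exactly the expected fix count for
    ``interval_minutes`` (24/48/96) and every gap is within
    ±`SPACING_TOLERANCE_MIN` of the nominal schedule.  Returns
    ``(day_tracks, exclusion_log)`` where the log has one row per excluded
    animal-day with a reason.
    """
    if interval_minutes not in FIXES_PER_DAY:
        raise ValueError(f"interval_minutes must be one of {sorted(FIXES_PER_DAY)}")
    tz = timezone or fixes.attrs.get("local_timezone", DEFAULT_TIMEZONE)
    expected = FIXES_PER_DAY[interval_minutes]
    tracks: list[DayTrack] = []
    excluded: list[dict] = []
    if len(fixes) == 0:
        return tracks, pd.DataFrame(columns=["animal_id", "date", "n_fixes", "reason"])
    local_date = fixes["timestamp"].dt.tz_convert(tz).dt.date
    for (animal, date), grp in fixes.groupby([fixes["animal_id"], local_date], sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        if len(grp) != expected:
            excluded.append(
                {"animal_id": animal, "date": date, "n_fixes": len(grp),
                 "reason": f"incomplete: {len(grp)}/{expected} fixes"}
            )
            continue
        gaps = grp["timestamp"].diff().dropna().dt.total_seconds() / 60.0
        if (np.abs(gaps.to_numpy() - interval_minutes) > SPACING_TOLERANCE_MIN).any():
            excluded.append(
                {"animal_id": animal, "date": date, "n_fixes": len(grp),
                 "reason": "irregular spacing"}
            )
            continue
        tracks.append(DayTrack(str(animal), date, interval_minutes, grp))
    if excluded:
        logger.info("build_day_tracks: excluded %d incomplete/irregular days", len(excluded))
    return tracks, pd.DataFrame(excluded, columns=["animal_id", "date", "n_fixes", "reason"])


def augment_to_hourly(day_track: DayTrack) -> list[DayTrack]:
    """Subset a day-track into independent hourly day-tracks.

    Hourly input yields itself; half-hourly data provides two independent
    hourly day-tracks (offsets 0 and 1); quarter-hourly provides four
    (offsets 0..3).  The union of the outputs' fixes is exactly the input's
    fixes, so no information is duplicated between augmented tracks.
    """
    k = 60 // day_track.interval_minutes
    if day_track.n_fixes != FIXES_PER_DAY[day_track.interval_minutes]:
        raise ValueError("augment_to_hourly requires a complete day-track")
    if k == 1:
        return [day_track]
    out = []
    for offset in range(k):
        sub = day_track.fixes.iloc[offset::k].reset_index(drop=True)
        out.append(
            DayTrack(day_track.animal_id, day_track.date, 60, sub, offset_index=offset)
        )
    return out


def augmentation_yield(n_hourly: int, n_half_hourly: int, n_quarter_hourly: int) -> dict:
    """Augmented hourly day-track counts from raw day counts per frequency.

    Hourly days contribute 1 track each, half-hourly 2, quarter-hourly 4.
    """
    out = {
        "hourly": n_hourly,
        "half_hourly": 2 * n_half_hourly,
        "quarter_hourly": 4 * n_quarter_hourly,
    }
    out["total"] = sum(out.values())
    return out


# ---------------------------------------------------------------------------
# Local metric projection
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LocalProjection:
    """Spherical azimuthal equidistant projection about a local centre.

    Distances from the centre are exact; distances between nearby points are
    accurate to well under 1% at the daily-movement scales used here.  The
    forward/inverse pair is closed-form and round-trips exactly.
    """

    lon0: float
    lat0: float
    radius: float = EARTH_RADIUS_M

    def forward(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lam = np.radians(np.asarray(lon, dtype=float)) - np.radians(self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        with np.errstate(invalid="ignore"):
            k = np.where(c > 1e-12, c / np.sin(c), 1.0)
        x = self.radius * k * np.cos(phi) * np.sin(lam)
        y = self.radius * k * (np.cos(phi0) * np.sin(phi)
                               - np.sin(phi0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float) / self.radius
        y = np.asarray(y, dtype=float) / self.radius
        c = np.hypot(x, y)
        phi0 = np.radians(self.lat0)
        safe_c = np.where(c > 1e-12, c, 1.0)
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.where(
            c > 1e-12,
            np.arcsin(np.clip(cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / safe_c,
                              -1.0, 1.0)),
            phi0,
        )
        lam = np.where(
            c > 1e-12,
            np.arctan2(x * sin_c,
                       safe_c * np.cos(phi0) * cos_c - y * np.sin(phi0) * sin_c),
            0.0,
        )
        return np.degrees(lam) + self.lon0, np.degrees(phi)


def project_fixes(fixes: pd.DataFrame, projection: LocalProjection | None = None) -> pd.DataFrame:
    """Fill metric ``x, y`` columns from ``lon, lat``.

    With no projection given, an azimuthal equidistant projection centred on
    the fix centroid is used, so coordinates are metres about the data centre
    anywhere on Earth.
    """
    if projection is None:
        projection = LocalProjection(float(fixes["lon"].mean()), float(fixes["lat"].mean()))
    if not fixes["lat"].between(-89.999, 89.999).all():
        bad = fixes.loc[~fixes["lat"].between(-89.999, 89.999)]
        raise ValueError(f"fixes outside projection validity (poles): rows {list(bad.index)}")
    x, y = projection.forward(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    out = fixes.assign(x=x, y=y)
    out.attrs.update(fixes.attrs)
    out.attrs["projection"] = projection
    return out


def write_tracks(fixes: pd.DataFrame, path) -> None:
    """Write a fix table in the package CSV dialect (ISO-8601 UTC)."""
    out = fixes[["animal_id", "timestamp", "lon", "lat"]].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def write_day_index(tracks: Sequence[DayTrack], excluded: pd.DataFrame, path) -> None:
    """Write the day-track index CSV (one row per candidate animal-day)."""
    rows = [
        {"animal_id": t.animal_id, "date": t.date, "interval": t.interval_minutes,
         "offset": t.offset_index, "n_fixes": t.n_fixes, "included": True}
        for t in tracks
    ]
    for _, r in excluded.iterrows():
        rows.append({"animal_id": r["animal_id"], "date": r["date"], "interval": np.nan,
                     "offset": np.nan, "n_fixes": r["n_fixes"], "included": False})
    pd.DataFrame(rows).to_csv(path, index=False)
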