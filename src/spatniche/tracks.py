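"""Reading, validating, cleaning and projecting GPS fix tables.

A *fix* is one GPS relocation: an individual id, a timestamp and a
longitude/latitude pair, optionally already projected to metric easting/
northing.  Fix tables are Movebank-like CSVs; the column names are remappable.

Cleaning emulates the manual removal of bad satellite fixes in field
studies with two automatic rules: fixes outside the nightly tracking window
are dropped, and a fix is dropped when the straight-line speed from the
previous retained fix of the same individual exceeds a cap (default 25 m/s,
a generous upper bound for bat flight).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import time as dtime

import numpy as np
import pandas as pd

__all__ = [
    "NightWindow",
    "TrackSet",
    "read_tracks",
    "clean_tracks",
    "project_tracks",
    "utm_zone_from_lon",
    "lonlat_to_utm",
    "utm_to_lonlat",
]

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "individual_id": "individual_id",
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
}


@dataclass(frozen=True)
class NightWindow:
    """Nightly sampling window on the local clock, possibly crossing midnight.

    Both endpoints are included, so a window 20:00-7:00 sampled at 10-minute
    steps has 67 slots per night.
    """

    start: dtime
    end: dtime
    utc_offset_hours: int = 8

    @classmethod
    def parse(cls, start: str, end: str, utc_offset_hours: int = 8) -> "NightWindow":
        return cls(dtime.fromisoformat(start), dtime.fromisoformat(end), utc_offset_hours)

    def contains(self, t: dtime) -> bool:
        m = t.hour * 60 + t.minute
        s = self.start.hour * 60 + self.start.minute
        e = self.end.hour * 60 + self.end.minute
        if s <= e:
            return s <= m <= e
        return m >= s or m <= e  # crosses midnight

    def minutes(self) -> int:
        s = self.start.hour * 60 + self.start.minute
        e = self.end.hour * 60 + self.end.minute
        return e - s if s <= e else 24 * 60 - s + e

    def n_slots(self, interval_minutes: int = 10) -> int:
        return self.minutes() // interval_minutes + 1


SUMMER_WINDOW = NightWindow.parse("20:00", "07:00", 8)
AUTUMN_WINDOW = NightWindow.parse("19:00", "07:00", 8)


@dataclass
class TrackSet:
    """Cleaned, canonically sorted GPS fixes for one season.

    ``fixes`` always has an ``individual_id`` column; ``timestamp``,
    ``lon``/``lat`` and projected ``x``/``y`` (metres) are present depending
    on provenance.  Rows are sorted by (individual_id, timestamp).
    """

    fixes: pd.DataFrame
    season: str = "summer"
    schedule: NightWindow | None = None
    crs: str | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fixes = _canonical_sort(self.fixes)

    @classmethod
    def from_points(
        cls,
        points_by_individual: dict[str, np.ndarray],
        season: str = "summer",
        schedule: NightWindow | None = None,
    ) -> "TrackSet":
        """Build a TrackSet from bare projected coordinates (metres)."""
        frames = []
        for ind, pts in points_by_individual.items():
            pts = np.asarray(pts, dtype=float)
            frames.append(pd.DataFrame({"individual_id": ind, "x": pts[:, 0], "y": pts[:, 1]}))
        return cls(pd.concat(frames, ignore_index=True), season=season, schedule=schedule)

    def individuals(self) -> list[str]:
        return sorted(self.fixes["individual_id"].unique())

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    def points(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    def points_by_individual(self) -> dict[str, np.ndarray]:
        return {
            ind: g[["x", "y"]].to_numpy(dtype=float)
            for ind, g in self.fixes.groupby("individual_id", sort=True)
        }

    def with_fixes(self, fixes: pd.DataFrame) -> "TrackSet":
        return replace(self, fixes=fixes.reset_index(drop=True))


def _canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    keys = [k for k in ("individual_id", "timestamp") if k in df.columns]
    if keys:
        df = df.sort_values(keys, kind="stable").reset_index(drop=True)
    return df


def read_tracks(
    path,
    column_map: dict[str, str] | None = None,
    season: str = "summer",
    schedule: NightWindow | None = None,
) -> TrackSet:
    """Read a GPS fix CSV into a :class:`TrackSet`.

    Malformed rows (unparseable timestamps, out-of-range coordinates,
    duplicate (id, timestamp) pairs) are rejected, counted in
    ``TrackSet.report`` and logged; they are never dropped silently.

    Raises ``KeyError`` when a mapped column is missing and ``ValueError``
    when no parseable rows remain.
    """
    colmap = {**DEFAULT_COLUMNS, **(column_map or {})}
    raw = pd.read_csv(path)
    missing = [c for c in colmap.values() if c not in raw.columns]
    if missing:
        raise KeyError(f"missing required column(s) {missing} in {path}")

    df = raw.rename(columns={v: k for k, v in colmap.items()})
    n_in = len(df)
    reasons: dict[str, int] = {}

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad_ts = ts.isna()
    reasons["unparseable_timestamp"] = int(bad_ts.sum())
    df = df.assign(timestamp=ts)

    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad_coord = (
        lon.isna() | lat.isna() | (lon.abs() > 180.0) | (lat.abs() > 90.0)
    ) & ~bad_ts
    reasons["invalid_coordinates"] = int(bad_coord.sum())
    df = df.assign(lon=lon, lat=lat)

    keep = ~(bad_ts | bad_coord)
    df = df.loc[keep]
    dup = df.duplicated(subset=["individual_id", "timestamp"], keep="first")
    reasons["duplicate_fix"] = int(dup.sum())
    df = df.loc[~dup]

    if df.empty:
        raise ValueError(f"no parseable GPS fixes in {path}")
    n_rejected = n_in - len(df)
    if n_rejected:
        logger.warning("read_tracks: rejected %d/%d rows (%s)", n_rejected, n_in, reasons)
    report = {"n_input": n_in, "n_parsed": len(df), "n_rejected": n_rejected, "reasons": reasons}
    return TrackSet(df, season=season, schedule=schedule, report=report)


# --- UTM projection (WGS84, Krüger series) ---------------------------------
#
# Forward/inverse transverse Mercator on the WGS84 ellipsoid using the
# classical 6th-order series; sub-metre accuracy within a UTM zone, far
# below GPS fix error.

_R = 6378137.0
_E = 0.00669438  # first eccentricity squared
_E2 = _E * _E
_E3 = _E2 * _E
_E_P2 = _E / (1.0 - _E)
_K0 = 0.9996
_SQRT_E = math.sqrt(1.0 - _E)
__E = (1.0 - _SQRT_E) / (1.0 + _SQRT_E)
__E2 = __E * __E
__E3 = __E2 * __E
__E4 = __E3 * __E
_M1 = 1.0 - _E / 4.0 - 3.0 * _E2 / 64.0 - 5.0 * _E3 / 256.0
_M2 = 3.0 * _E / 8.0 + 3.0 * _E2 / 32.0 + 45.0 * _E3 / 1024.0
_M3 = 15.0 * _E2 / 256.0 + 45.0 * _E3 / 1024.0
_M4 = 35.0 * _E3 / 3072.0
_P2 = 3.0 / 2.0 * __E - 27.0 / 32.0 * __E3
_P3 = 21.0 / 16.0 * __E2 - 55.0 / 32.0 * __E4
_P4 = 151.0 / 96.0 * __E3
_P5 = 1097.0 / 512.0 * __E4


def utm_zone_from_lon(lon: float) -> int:
    return int((lon + 180.0) // 6.0) + 1


def lonlat_to_utm(lon, lat, zone: int) -> tuple[np.ndarray, np.ndarray]:
    """Project longitude/latitude (degrees) to UTM easting/northing (metres)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 84.0):
        bad = np.flatnonzero(np.abs(lat) > 84.0)
        raise ValueError(f"latitude outside UTM domain at row(s) {bad[:5].tolist()}")
    lat_r = np.radians(lat)
    central = math.radians(zone * 6 - 183)
    lon_r = np.radians(lon) - central

    sin_l, cos_l, tan_l = np.sin(lat_r), np.cos(lat_r), np.tan(lat_r)
    n = _R / np.sqrt(1.0 - _E * sin_l**2)
    c = _E_P2 * cos_l**2
    a = cos_l * lon_r
    a2, a3, a4, a5, a6 = a * a, a**3, a**4, a**5, a**6
    t = tan_l**2
    m = _R * (
        _M1 * lat_r
        - _M2 * np.sin(2 * lat_r)
        + _M3 * np.sin(4 * lat_r)
        - _M4 * np.sin(6 * lat_r)
    )
    easting = (
        _K0 * n * (a + a3 / 6 * (1 - t + c) + a5 / 120 * (5 - 18 * t + t * t + 72 * c - 58 * _E_P2))
        + 500000.0
    )
    northing = _K0 * (
        m
        + n
        * tan_l
        * (
            a2 / 2
            + a4 / 24 * (5 - t + 9 * c + 4 * c * c)
            + a6 / 720 * (61 - 58 * t + t * t + 600 * c - 330 * _E_P2)
        )
    )
    northing = np.where(lat < 0, northing + 10000000.0, northing)
    return easting, northing


def utm_to_lonlat(easting, northing, zone: int, northern: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Inverse UTM projection back to longitude/latitude (degrees)."""
    x = np.asarray(easting, dtype=float) - 500000.0
    y = np.asarray(northing, dtype=float)
    if not northern:
        y = y - 10000000.0

    m = y / _K0
    mu = m / (_R * _M1)
    p_rad = (
        mu
        + _P2 * np.sin(2 * mu)
        + _P3 * np.sin(4 * mu)
        + _P4 * np.sin(6 * mu)
        + _P5 * np.sin(8 * mu)
    )
    p_sin, p_cos = np.sin(p_rad), np.cos(p_rad)
    p_tan = p_sin / p_cos
    p_tan2, p_tan4 = p_tan * p_tan, p_tan**4
    ep_sin = 1.0 - _E * p_sin**2
    ep_sin_sqrt = np.sqrt(ep_sin)
    n = _R / ep_sin_sqrt
    r = (1.0 - _E) / ep_sin
    c = _E_P2 * p_cos**2
    c2 = c * c
    d = x / (n * _K0)
    d2, d3, d4, d5, d6 = d * d, d**3, d**4, d**5, d**6

    lat = p_rad - (p_tan / r) * (
        d2 / 2
        - d4 / 24 * (5 + 3 * p_tan2 + 10 * c - 4 * c2 - 9 * _E_P2)
        + d6 / 720 * (61 + 90 * p_tan2 + 298 * c + 45 * p_tan4 - 252 * _E_P2 - 3 * c2)
    )
    lon = (
        d
        - d3 / 6 * (1 + 2 * p_tan2 + c)
        + d5 / 120 * (5 - 2 * c + 28 * p_tan2 - 3 * c2 + 8 * _E_P2 + 24 * p_tan4)
    ) / p_cos
    central = math.radians(zone * 6 - 183)
    return np.degrees(lon + central), np.degrees(lat)


def project_tracks(ts: TrackSet, zone: int | None = None) -> TrackSet:
    """Fill metric ``x``/``y`` columns by UTM projection of lon/lat.

    The zone defaults to the UTM zone of the mean longitude.  The CRS used
    is recorded in ``TrackSet.crs``.
    """
    df = ts.fixes.copy()
    if "lon" not in df.columns or "lat" not in df.columns:
        raise ValueError("TrackSet has no lon/lat columns to project")
    if zone is None:
        zone = utm_zone_from_lon(float(df["lon"].mean()))
    x, y = lonlat_to_utm(df["lon"].to_numpy(), df["lat"].to_numpy(), zone)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        bad = int(np.flatnonzero(~(np.isfinite(x) & np.isfinite(y)))[0])
        raise ValueError(f"unprojectable coordinates at fix row {bad}")
    df["x"], df["y"] = x, y
    northern = bool(df["lat"].mean() >= 0)
    out = ts.with_fixes(df)
    out.crs = f"UTM zone {zone}{'N' if northern else 'S'} (WGS84)"
    return out


def clean_tracks(
    ts: TrackSet,
    max_speed: float = 25.0,
    schedule: NightWindow | None = None,
) -> tuple[TrackSet, dict]:
    """Drop fixes outside the nightly window or implying implausible speed.

    The speed rule is sequential per individual: a fix is removed when the
    straight-line speed from the previous *retained* fix of the same
    individual exceeds ``max_speed`` (m/s).  Returns the cleaned TrackSet
    and a removal report with counts by reason.  Idempotent.
    """
    if max_speed <= 0:
        raise ValueError("max_speed must be positive")
    schedule = schedule or ts.schedule
    df = ts.fixes
    if ("x" not in df.columns or "y" not in df.columns) and "lon" in df.columns:
        ts = project_tracks(ts)
        df = ts.fixes
    n_in = len(df)

    if schedule is not None and "timestamp" in df.columns:
        local = df["timestamp"]
        if local.dt.tz is not None:
            local = local.dt.tz_convert(f"UTC+{schedule.utc_offset_hours:02d}:00")
        in_window = local.dt.time.map(schedule.contains)
        n_window = int((~in_window).sum())
        df = df.loc[in_window]
    else:
        n_window = 0

    keep_idx: list[int] = []
    n_speed = 0
    for _, g in df.groupby("individual_id", sort=False):
        has_time = "timestamp" in g.columns and g["timestamp"].notna().all()
        prev = None
        for idx, row in g.iterrows():
            if prev is None or not has_time:
                keep_idx.append(idx)
                prev = row
                continue
            dt = (row["timestamp"] - prev["timestamp"]).total_seconds()
            dist = math.hypot(row["x"] - prev["x"], row["y"] - prev["y"])
            if dt > 0 and dist / dt > max_speed:
                n_speed += 1
            else:
                keep_idx.append(idx)
                prev = row
    out_df = df.loc[keep_idx]

    lost = [
        ind
        for ind in ts.individuals()
        if ind not in set(out_df["individual_id"])
    ]
    for ind in lost:
        logger.warning("clean_tracks: all fixes of individual %r removed", ind)
    report = {
        "n_input": n_in,
        "n_output": len(out_df),
        "removed_outside_window": n_window,
        "removed_speed": n_speed,
        "individuals_fully_removed": lost,
    }
    return ts.with_fixes(out_df), report
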