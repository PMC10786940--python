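"""Geodesic arithmetic and the weekly social-mobility index.

The social-mobility index of a user-week is the radius of gyration of the
week's geotagged locations: the root-mean-square great-circle distance from
each post to the week's spherical centroid, in kilometres.  A week in which
every post carries the same coordinate has index 0; a week spent ranging over
a city has an index on the order of the city's extent.

Two layers are provided: small typed objects (:class:`GeoPoint`,
:class:`GeoPost`, :class:`UserWeekMobility`) with scalar operations for
clarity, and vectorised table functions (:func:`weekly_mobility_table`) that
do the same arithmetic over millions of posts with numpy group reductions.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "GeoPost",
    "UserWeekMobility",
    "ValidationError",
    "haversine_km",
    "spherical_centroid",
    "weekly_mobility_index",
    "user_mobility_series",
    "weekly_mobility_table",
    "iso_week_key",
    "week_monday",
]

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


class ValidationError(ValueError):
    """Raised for out-of-range or malformed coordinates and records."""


def _check_latlon(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValidationError("non-finite coordinate")
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise ValidationError("latitude outside [-90, 90]")
    if np.any(lon <= -180.0) or np.any(lon > 180.0):
        # callers should normalize first via normalize_lon
        raise ValidationError("longitude outside (-180, 180]")


def normalize_lon(lon):
    """Map longitudes into (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = ((lon + 180.0) % 360.0) - 180.0
    out = np.where(out == -180.0, 180.0, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclasses.dataclass(frozen=True)
class GeoPoint:
    """A WGS84 coordinate in decimal degrees.

    Longitude is normalised into (-180, 180] on construction.
    """

    lat: float
    lon: float

    def __post_init__(self):
        lon = normalize_lon(self.lon)
        object.__setattr__(self, "lon", float(lon))
        object.__setattr__(self, "lat", float(self.lat))
        _check_latlon(self.lat, self.lon)


@dataclasses.dataclass(frozen=True)
class GeoPost:
    """One geotagged post: opaque user id, UTC instant, coordinate."""

    user_id: str
    ts: _dt.datetime
    point: GeoPoint

    def __post_init__(self):
        if self.ts.tzinfo is None:
            raise ValidationError(
                f"naive timestamp for user {self.user_id!r}; UTC required"
            )


@dataclasses.dataclass(frozen=True)
class UserWeekMobility:
    """One user-week: post count, weekly centroid and mobility index (km)."""

    user_id: str
    iso_year: int
    iso_week: int
    n_posts: int
    centroid: GeoPoint
    index_km: float

    @property
    def week_key(self) -> tuple[int, int]:
        return (self.iso_year, self.iso_week)


# ---------------------------------------------------------------------------
# distances and centroids


def _as_latlon(p) -> tuple[float, float]:
    if isinstance(p, GeoPoint):
        return p.lat, p.lon
    lat, lon = p
    return float(lat), float(lon)


def haversine_km(a, b) -> float:
    """Great-circle distance between two points, km.

    Uses the haversine formula on a sphere of radius ``EARTH_RADIUS_KM``.
    Accepts :class:`GeoPoint` or ``(lat, lon)`` pairs.
    """
    lat1, lon1 = _as_latlon(a)
    lat2, lon2 = _as_latlon(b)
    lon1 = normalize_lon(lon1)
    lon2 = normalize_lon(lon2)
    _check_latlon(lat1, lon1)
    _check_latlon(lat2, lon2)
    return float(haversine_km_arrays(lat1, lon1, lat2, lon2))


def haversine_km_arrays(lat1, lon1, lat2, lon2):
    """Vectorised haversine; inputs in degrees, output km. No validation."""
    lat1 = np.deg2rad(np.asarray(lat1, dtype=float))
    lat2 = np.deg2rad(np.asarray(lat2, dtype=float))
    dlat = lat2 - lat1
    dlon = np.deg2rad(np.asarray(lon2, dtype=float)) - np.deg2rad(
        np.asarray(lon1, dtype=float)
    )
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    )
    # clip guards rounding for antipodal pairs
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _unit_vectors(lat, lon):
    lat = np.deg2rad(np.asarray(lat, dtype=float))
    lon = np.deg2rad(np.asarray(lon, dtype=float))
    cos_lat = np.cos(lat)
    return cos_lat * np.cos(lon), cos_lat * np.sin(lon), np.sin(lat)


def _vectors_to_latlon(x, y, z):
    norm = np.sqrt(x * x + y * y + z * z)
    lat = np.rad2deg(np.arcsin(np.clip(z / norm, -1.0, 1.0)))
    lon = np.rad2deg(np.arctan2(y, x))
    return lat, normalize_lon(lon)


#: mean unit vectors shorter than this are treated as degenerate
_DEGENERATE_NORM = 1e-9


def spherical_centroid(points: Sequence) -> GeoPoint:
    """Spherical centroid: normalised 3-D mean of the unit position vectors.

    Deterministic and permutation-invariant.  Raises
    :class:`ValidationError` on an empty list or a near-antipodal set whose
    mean vector vanishes.
    """
    pts = [_as_latlon(p) for p in points]
    if not pts:
        raise ValidationError("spherical_centroid of empty point list")
    lat = np.array([p[0] for p in pts])
    lon = normalize_lon(np.array([p[1] for p in pts]))
    _check_latlon(lat, lon)
    x, y, z = _unit_vectors(lat, lon)
    mx, my, mz = x.mean(), y.mean(), z.mean()
    if np.sqrt(mx * mx + my * my + mz * mz) < _DEGENERATE_NORM:
        raise ValidationError("degenerate centroid: mean vector near zero")
    clat, clon = _vectors_to_latlon(mx, my, mz)
    return GeoPoint(float(clat), float(clon))


# ---------------------------------------------------------------------------
# ISO week handling


def iso_week_key(ts: _dt.datetime | _dt.date) -> tuple[int, int]:
    """(ISO year, ISO week) of a UTC timestamp's date."""
    if isinstance(ts, _dt.datetime):
        ts = ts.date()
    iso = ts.isocalendar()
    return (iso[0], iso[1])


def week_monday(iso_year: int, iso_week: int) -> _dt.date:
    """The Monday starting the given ISO week."""
    return _dt.date.fromisocalendar(int(iso_year), int(iso_week), 1)


# ---------------------------------------------------------------------------
# the weekly index


def _gyration_index(lat, lon, ddof: int = 0) -> tuple[GeoPoint, float]:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.all(lat == lat[0]) and np.all(lon == lon[0]):
        # exact zero for a single repeated location
        return GeoPoint(float(lat[0]), float(lon[0])), 0.0
    centroid = spherical_centroid(list(zip(lat, lon)))
    d = haversine_km_arrays(lat, lon, centroid.lat, centroid.lon)
    n = d.size
    if n - ddof <= 0:
        return centroid, 0.0
    return centroid, float(np.sqrt(np.sum(d * d) / (n - ddof)))


def _consecutive_index(lat, lon, ddof: int = 0) -> float:
    # sensitivity variant: dispersion of consecutive check-in distances
    if len(lat) < 2:
        return 0.0
    d = haversine_km_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:])
    if d.size - ddof <= 0:
        return 0.0
    return float(np.sqrt(np.sum((d - d.mean()) ** 2) / (d.size - ddof)))


def weekly_mobility_index(
    posts: Sequence[GeoPost], *, variant: str = "gyration", ddof: int = 0
) -> UserWeekMobility:
    """Mobility index for one user-week.

    With the default ``variant="gyration"`` (population form, ``ddof=0``)::

        index_km = sqrt( mean_i  haversine(p_i, centroid)^2 )

    Repeated identical coordinates each count.  ``variant="consecutive"``
    instead takes the standard deviation of consecutive check-in distances
    (a sensitivity alternative; the default is the standard mobility
    statistic).

    All posts must share one user and one ISO week.
    """
    posts = list(posts)
    if not posts:
        raise ValidationError("weekly_mobility_index of empty post list")
    users = {p.user_id for p in posts}
    weeks = {iso_week_key(p.ts) for p in posts}
    if len(users) > 1:
        raise ValidationError(f"posts span multiple users: {sorted(users)}")
    if len(weeks) > 1:
        raise ValidationError(f"posts span multiple weeks: {sorted(weeks)}")
    posts = sorted(posts, key=lambda p: p.ts)
    lat = np.array([p.point.lat for p in posts])
    lon = np.array([p.point.lon for p in posts])
    centroid, idx = _gyration_index(lat, lon, ddof=ddof)
    if variant == "consecutive":
        idx = _consecutive_index(lat, lon, ddof=ddof)
    elif variant != "gyration":
        raise ValueError(f"unknown index variant {variant!r}")
    (iso_year, iso_week) = next(iter(weeks))
    return UserWeekMobility(
        user_id=posts[0].user_id,
        iso_year=iso_year,
        iso_week=iso_week,
        n_posts=len(posts),
        centroid=centroid,
        index_km=idx,
    )


def user_mobility_series(
    posts: Iterable[GeoPost], *, variant: str = "gyration", ddof: int = 0
) -> list[UserWeekMobility]:
    """Per-week mobility indices for one user, sorted by ISO week key.

    Weeks without posts are simply absent from the series (no geotagged
    activity is not evidence of zero movement); downstream period means may
    optionally impute them as zero.
    """
    by_week: dict[tuple[int, int], list[GeoPost]] = {}
    users = set()
    for p in posts:
        users.add(p.user_id)
        by_week.setdefault(iso_week_key(p.ts), []).append(p)
    if len(users) > 1:
        raise ValidationError(f"posts span multiple users: {sorted(users)}")
    return [
        weekly_mobility_index(by_week[k], variant=variant, ddof=ddof)
        for k in sorted(by_week)
    ]


# ---------------------------------------------------------------------------
# vectorised table path


def weekly_mobility_table(
    posts: pd.DataFrame, *, variant: str = "gyration", ddof: int = 0
) -> pd.DataFrame:
    """Weekly mobility index for every user-week in a posts table.

    Parameters
    ----------
    posts
        Columns ``user_id``, ``ts`` (timezone-aware datetime64), ``lat``,
        ``lon``.  ``user_id`` may be a pandas Categorical for speed.
    variant, ddof
        As in :func:`weekly_mobility_index`.

    Returns
    -------
    DataFrame with columns ``user_id, iso_year, iso_week, n_posts,
    centroid_lat, centroid_lon, index_km``, sorted by user then week.
    """
    if posts.empty:
        return pd.DataFrame(
            columns=[
                "user_id",
                "iso_year",
                "iso_week",
                "n_posts",
                "centroid_lat",
                "centroid_lon",
                "index_km",
            ]
        )
    lat = posts["lat"].to_numpy(dtype=float)
    lon = normalize_lon(posts["lon"].to_numpy(dtype=float))
    _check_latlon(lat, lon)

    iso = posts["ts"].dt.isocalendar()
    iso_year = iso["year"].to_numpy(dtype=np.int32)
    iso_week = iso["week"].to_numpy(dtype=np.int32)

    user_codes, user_index = pd.factorize(posts["user_id"], sort=True)
    week_id = iso_year.astype(np.int64) * 54 + iso_week
    combo = user_codes.astype(np.int64) * 200_000 + week_id
    codes, uniq = pd.factorize(combo, sort=True)
    n_groups = len(uniq)
    counts = np.bincount(codes, minlength=n_groups)

    x, y, z = _unit_vectors(lat, lon)
    mx = np.bincount(codes, weights=x, minlength=n_groups) / counts
    my = np.bincount(codes, weights=y, minlength=n_groups) / counts
    mz = np.bincount(codes, weights=z, minlength=n_groups) / counts
    norm = np.sqrt(mx * mx + my * my + mz * mz)
    if np.any(norm < _DEGENERATE_NORM):
        bad = int(np.argmax(norm < _DEGENERATE_NORM))
        raise ValidationError(
            f"degenerate weekly centroid (antipodal points) in group {bad}"
        )
    clat, clon = _vectors_to_latlon(mx, my, mz)

    d = haversine_km_arrays(lat, lon, clat[codes], clon[codes])
    ss = np.bincount(codes, weights=d * d, minlength=n_groups)
    denom = counts - ddof
    with np.errstate(invalid="ignore", divide="ignore"):
        index_km = np.where(denom > 0, np.sqrt(ss / np.maximum(denom, 1)), 0.0)

    # exact zero for weeks whose posts all share one coordinate
    order = np.argsort(codes, kind="stable")
    first_idx = order[np.r_[0, np.cumsum(counts[:-1])]]
    mismatch = (lat != lat[first_idx][codes]) | (lon != lon[first_idx][codes])
    n_mismatch = np.bincount(codes, weights=mismatch, minlength=n_groups)
    index_km = np.where(n_mismatch == 0, 0.0, index_km)

    out = pd.DataFrame(
        {
            "user_id": pd.Series(
                user_index[(uniq // 200_000).astype(np.int64)], dtype="object"
            ),
            "iso_year": ((uniq % 200_000) // 54).astype(np.int32),
            "iso_week": ((uniq % 200_000) % 54).astype(np.int32),
            "n_posts": counts.astype(np.int64),
            "centroid_lat": clat,
            "centroid_lon": clon,
            "index_km": index_km,
        }
    )
    if variant == "consecutive":
        out["index_km"] = _consecutive_table_index(
            posts, lat, lon, combo, ddof
        ).loc[uniq].to_numpy()
    elif variant != "gyration":
        raise ValueError(f"unknown index variant {variant!r}")
    return out.reset_index(drop=True)


def _consecutive_table_index(posts, lat, lon, combo, ddof):
    # slower path, used only for the sensitivity variant
    order = np.lexsort((posts["ts"].to_numpy(), combo))
    combo_s, lat_s, lon_s = combo[order], lat[order], lon[order]
    df = pd.DataFrame({"g": combo_s, "lat": lat_s, "lon": lon_s})

    def _one(sub):
        return _consecutive_index(
            sub["lat"].to_numpy(), sub["lon"].to_numpy(), ddof=ddof
        )

    return df.groupby("g", sort=True).apply(_one, include_groups=False)
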