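"""Geodesy and weekly-index tests against independent oracles."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as stn

from socmob.geo import (
    EARTH_RADIUS_KM,
    GeoPoint,
    GeoPost,
    ValidationError,
    haversine_km,
    spherical_centroid,
    user_mobility_series,
    weekly_mobility_index,
    weekly_mobility_table,
)

from conftest import utc

# ---------------------------------------------------------------------------
# independent oracles (deliberately different formulas/code paths)


def sloc_distance_km(a, b):
    """Spherical law of cosines, independent of the haversine path."""
    p1, l1, p2, l2 = map(math.radians, (a[0], a[1], b[0], b[1]))
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(
        l2 - l1
    )
    return EARTH_RADIUS_KM * math.acos(min(1.0, max(-1.0, c)))


def mean_vector_centroid(points):
    """Brute-force 3-D mean + renormalisation, coded from scratch."""
    xs = ys = zs = 0.0
    for lat, lon in points:
        phi, lam = math.radians(lat), math.radians(lon)
        xs += math.cos(phi) * math.cos(lam)
        ys += math.cos(phi) * math.sin(lam)
        zs += math.sin(phi)
    n = len(points)
    xs, ys, zs = xs / n, ys / n, zs / n
    r = math.sqrt(xs * xs + ys * ys + zs * zs)
    return (
        math.degrees(math.asin(zs / r)),
        math.degrees(math.atan2(ys, xs)),
    )


def random_points(rng, n, lat_range=(-80, 80)):
    lat = rng.uniform(*lat_range, size=n)
    lon = rng.uniform(-179.0, 179.0, size=n)
    return list(zip(lat, lon))


# ---------------------------------------------------------------------------
# haversine


def test_haversine_identity_is_zero():
    assert haversine_km((10, 20), (10, 20)) == 0.0


def test_haversine_antipodal_closed_form():
    assert haversine_km((0, 0), (0, 180)) == pytest.approx(
        math.pi * EARTH_RADIUS_KM, rel=1e-12
    )


def test_haversine_matches_law_of_cosines_oracle(rng):
    for _ in range(10):
        a, b = random_points(rng, 2)
        d = haversine_km(a, b)
        assert d == pytest.approx(sloc_distance_km(a, b), rel=1e-6)


@pytest.mark.parametrize(
    "bad",
    [(91.0, 0.0), (float("nan"), 0.0), (-95.0, 10.0), (float("inf"), 0.0)],
)
def test_haversine_rejects_invalid_coordinates(bad):
    with pytest.raises(ValidationError):
        haversine_km(bad, (0.0, 0.0))


@settings(max_examples=100, derandomize=True)
@given(
    lat1=stn.floats(-90, 90),
    lon1=stn.floats(-179.99, 180),
    lat2=stn.floats(-90, 90),
    lon2=stn.floats(-179.99, 180),
)
def test_haversine_symmetric_and_nonnegative(lat1, lon1, lat2, lon2):
    d = haversine_km((lat1, lon1), (lat2, lon2))
    assert d >= 0.0
    assert d == pytest.approx(
        haversine_km((lat2, lon2), (lat1, lon1)), abs=1e-9
    )
    assert d <= math.pi * EARTH_RADIUS_KM + 1e-9


def test_haversine_zero_iff_equal_after_lon_normalization():
    assert haversine_km((45.0, 180.0), (45.0, -180.0 + 360.0)) == 0.0


# ---------------------------------------------------------------------------
# spherical centroid


def test_centroid_of_identical_points():
    c = spherical_centroid([(5, 5), (5, 5), (5, 5)])
    assert (c.lat, c.lon) == pytest.approx((5.0, 5.0), abs=1e-12)


def test_centroid_symmetry_about_equator():
    c = spherical_centroid([(1, 0), (-1, 0)])
    assert (c.lat, c.lon) == pytest.approx((0.0, 0.0), abs=1e-12)


def test_centroid_matches_mean_vector_oracle(rng):
    pts = random_points(rng, 5)
    c = spherical_centroid(pts)
    exp_lat, exp_lon = mean_vector_centroid(pts)
    assert c.lat == pytest.approx(exp_lat, abs=1e-9)
    assert c.lon == pytest.approx(exp_lon, abs=1e-9)


def test_centroid_permutation_invariant(rng):
    pts = random_points(rng, 7)
    c1 = spherical_centroid(pts)
    c2 = spherical_centroid(list(reversed(pts)))
    assert (c1.lat, c1.lon) == pytest.approx((c2.lat, c2.lon), abs=1e-12)


def test_centroid_empty_and_degenerate_errors():
    with pytest.raises(ValidationError):
        spherical_centroid([])
    with pytest.raises(ValidationError):
        spherical_centroid([(0.0, 0.0), (0.0, 180.0)])


# ---------------------------------------------------------------------------
# weekly index


def _posts(coords, user="u1", day0=utc(2019, 3, 4)):
    return [
        GeoPost(user, day0 + dt.timedelta(hours=i), GeoPoint(la, lo))
        for i, (la, lo) in enumerate(coords)
    ]


def test_single_post_week_has_zero_index():
    w = weekly_mobility_index(_posts([(40.0, -100.0)]))
    assert w.index_km == 0.0
    assert w.n_posts == 1


def test_repeated_coordinate_week_has_zero_index():
    w = weekly_mobility_index(_posts([(40.0, -100.0)] * 6))
    assert w.index_km == pytest.approx(0.0, abs=1e-9)


def test_two_posts_one_km_apart_give_half_km_index():
    # equatorial pair separated by 1 km of longitude
    dlon = 1.0 / (EARTH_RADIUS_KM * math.pi / 180.0)
    posts = _posts([(0.0, 10.0), (0.0, 10.0 + dlon)])
    gap = haversine_km(posts[0].point, posts[1].point)
    assert gap == pytest.approx(1.0, rel=1e-9)
    w = weekly_mobility_index(posts)
    assert w.index_km == pytest.approx(0.5, rel=1e-6)


def test_weekly_index_rejects_mixed_users_and_weeks():
    mixed_users = _posts([(1, 1)]) + _posts([(2, 2)], user="u2")
    with pytest.raises(ValidationError):
        weekly_mobility_index(mixed_users)
    two_weeks = _posts([(1, 1)]) + _posts([(2, 2)], day0=utc(2019, 3, 12))
    with pytest.raises(ValidationError):
        weekly_mobility_index(two_weeks)
    with pytest.raises(ValidationError):
        weekly_mobility_index([])


def test_weekly_index_permutation_invariant(rng):
    coords = random_points(rng, 9, lat_range=(30, 31))
    a = weekly_mobility_index(_posts(coords))
    b = weekly_mobility_index(_posts(list(reversed(coords))))
    assert a.index_km == pytest.approx(b.index_km, abs=1e-12)


def test_weekly_index_rotation_invariant(rng):
    coords = random_points(rng, 8, lat_range=(-50, 50))
    base = weekly_mobility_index(_posts(coords)).index_km
    shifted = [(la, ((lo + 73.0 + 180.0) % 360.0) - 180.0) for la, lo in coords]
    rot = weekly_mobility_index(_posts(shifted)).index_km
    assert rot == pytest.approx(base, abs=1e-6)


def test_weekly_index_bounded_by_max_distance(rng):
    coords = random_points(rng, 12, lat_range=(20, 25))
    w = weekly_mobility_index(_posts(coords))
    dmax = max(
        haversine_km((la, lo), (w.centroid.lat, w.centroid.lon))
        for la, lo in coords
    )
    assert w.index_km <= dmax + 1e-12


def test_weekly_index_matches_planar_gyration_in_small_limit(rng):
    # points within a few km: spherical index ~ tangent-plane gyration
    lat0, lon0 = 38.0, -95.0
    dx = rng.uniform(-4.0, 4.0, size=20)  # km east
    dy = rng.uniform(-4.0, 4.0, size=20)  # km north
    deg = 180.0 / math.pi
    coords = [
        (
            lat0 + (y / EARTH_RADIUS_KM) * deg,
            lon0 + (x / (EARTH_RADIUS_KM * math.cos(math.radians(lat0)))) * deg,
        )
        for x, y in zip(dx, dy)
    ]
    w = weekly_mobility_index(_posts(coords))
    planar = math.sqrt(
        np.mean((dx - dx.mean()) ** 2 + (dy - dy.mean()) ** 2)
    )
    assert w.index_km == pytest.approx(planar, rel=1e-3)


# ---------------------------------------------------------------------------
# per-user series and the vectorised table


def test_series_one_week():
    series = user_mobility_series(_posts([(3, 3), (3.1, 3.1)]))
    assert len(series) == 1


def test_series_three_weeks_sorted(rng):
    posts = []
    for k in range(3):
        posts += _posts(
            random_points(rng, 4, lat_range=(10, 11)),
            day0=utc(2019, 3, 4) + dt.timedelta(weeks=2 - k),
        )
    series = user_mobility_series(posts)
    keys = [s.week_key for s in series]
    assert len(series) == 3
    assert keys == sorted(keys)


def test_series_matches_per_week_brute_force(rng):
    posts = []
    for k in range(4):
        posts += _posts(
            random_points(rng, 5, lat_range=(35, 36)),
            day0=utc(2019, 6, 3) + dt.timedelta(weeks=k),
        )
    series = user_mobility_series(posts)
    for s in series:
        week_pts = [
            (p.point.lat, p.point.lon)
            for p in posts
            if p.ts.date().isocalendar()[:2] == (s.iso_year, s.iso_week)
        ]
        clat, clon = mean_vector_centroid(week_pts)
        expected = math.sqrt(
            np.mean(
                [sloc_distance_km(pt, (clat, clon)) ** 2 for pt in week_pts]
            )
        )
        assert s.index_km == pytest.approx(expected, rel=1e-6)


def test_table_agrees_with_scalar_path(rng):
    rows = []
    for u in ("alice", "bob"):
        for k in range(3):
            for la, lo in random_points(rng, 4, lat_range=(40, 41)):
                rows.append(
                    (u, utc(2019, 5, 6) + dt.timedelta(weeks=k, hours=la), la, lo)
                )
    posts = pd.DataFrame(rows, columns=["user_id", "ts", "lat", "lon"])
    posts["ts"] = pd.to_datetime(posts["ts"], utc=True)
    table = weekly_mobility_table(posts)
    assert len(table) == 6
    for _, r in table.iterrows():
        sub = posts[posts["user_id"] == r["user_id"]]
        keep = [
            GeoPost(r["user_id"], t.to_pydatetime(), GeoPoint(la, lo))
            for t, la, lo in zip(sub["ts"], sub["lat"], sub["lon"])
            if t.isocalendar()[:2] == (r["iso_year"], r["iso_week"])
        ]
        w = weekly_mobility_index(keep)
        assert r["index_km"] == pytest.approx(w.index_km, rel=1e-9)
        assert r["n_posts"] == w.n_posts


def test_table_variant_and_ddof_change_the_statistic(rng):
    rows = []
    for k, (la, lo) in enumerate(random_points(rng, 6, lat_range=(40, 41))):
        rows.append(("u", utc(2019, 5, 6) + dt.timedelta(hours=k), la, lo))
    posts = pd.DataFrame(rows, columns=["user_id", "ts", "lat", "lon"])
    posts["ts"] = pd.to_datetime(posts["ts"], utc=True)
    base = weekly_mobility_table(posts)["index_km"].iloc[0]
    sample = weekly_mobility_table(posts, ddof=1)["index_km"].iloc[0]
    consec = weekly_mobility_table(posts, variant="consecutive")["index_km"].iloc[0]
    assert sample > base  # 1/(n-1) > 1/n scaling
    assert sample == pytest.approx(base * math.sqrt(6 / 5), rel=1e-9)
    assert consec != pytest.approx(base, rel=1e-3)
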