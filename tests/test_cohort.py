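"""Cohort filters, labeling rules and covariate attachment."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from socmob.cohort import (
    StudyWindow,
    affiliation_from_follows,
    affiliation_from_state,
    attach_trust_and_risk,
    bin_age,
    box_state_assigner,
    density_category,
    density_category_table,
    filter_cohort,
    hashtag_flag,
    home_location,
    period_means,
    period_means_table,
    strip_trump_handle,
    trump_follow_flag,
    weighted_average,
)
from socmob.geo import GeoPoint, GeoPost, UserWeekMobility, ValidationError
from socmob.geo import week_monday

from conftest import utc


def uwm(user, year, week, index, n=3):
    return UserWeekMobility(user, year, week, n, GeoPoint(35.0, -95.0), index)


# ---------------------------------------------------------------------------
# period means


def test_period_means_simple_arithmetic(window):
    series = [
        uwm("u", 2019, 10, 10.0),
        uwm("u", 2019, 40, 10.0),
        uwm("u", 2020, 20, 4.0),
    ]
    mb, ma, red = period_means(series, window)
    assert (mb, ma, red) == (10.0, 4.0, 6.0)


def test_period_means_missing_period_flags_exclusion(window):
    after_only = [uwm("u", 2020, 20, 5.0)]
    mb, ma, red = period_means(after_only, window)
    assert math.isnan(mb) and ma == 5.0 and math.isnan(red)
    mb, ma, red = period_means([], window)
    assert math.isnan(mb) and math.isnan(ma)


def test_cut_week_monday_boundary(window):
    # 2020-03-16 is a Monday: ISO week 2020-W12 belongs to "after"
    assert week_monday(2020, 12) == window.cut
    series = [uwm("u", 2020, 11, 8.0), uwm("u", 2020, 12, 2.0)]
    mb, ma, _ = period_means(series, window)
    assert (mb, ma) == (8.0, 2.0)


def test_period_means_table_matches_scalar(rng, window):
    rows = []
    for u in range(20):
        for wk in sorted(rng.choice(np.arange(60), size=8, replace=False)):
            year, week = (2019, wk + 1) if wk < 52 else (2020, wk - 51)
            rows.append(
                {
                    "user_id": f"u{u}",
                    "iso_year": year,
                    "iso_week": week,
                    "n_posts": int(rng.integers(1, 9)),
                    "index_km": float(rng.gamma(2.0, 5.0)),
                }
            )
    weekly = pd.DataFrame(rows)
    table = period_means_table(weekly, window)
    for u, sub in weekly.groupby("user_id"):
        series = [
            uwm(u, r.iso_year, r.iso_week, r.index_km) for r in sub.itertuples()
        ]
        mb, ma, red = period_means(series, window)
        row = table.loc[u]
        for got, want in ((row.mean_before, mb), (row.mean_after, ma)):
            assert (math.isnan(want) and math.isnan(got)) or got == pytest.approx(want)


def test_empty_week_imputation_only_lowers_means(rng, window):
    rows = [
        {
            "user_id": "u",
            "iso_year": 2019,
            "iso_week": int(w),
            "n_posts": 2,
            "index_km": float(rng.gamma(2.0, 5.0)),
        }
        for w in (2, 9, 30)
    ] + [
        {"user_id": "u", "iso_year": 2020, "iso_week": 20, "n_posts": 2, "index_km": 7.0}
    ]
    weekly = pd.DataFrame(rows)
    plain = period_means_table(weekly, window)
    imputed = period_means_table(weekly, window, include_empty_weeks_as_zero=True)
    assert imputed.loc["u", "mean_before"] <= plain.loc["u", "mean_before"]
    assert imputed.loc["u", "mean_after"] <= plain.loc["u", "mean_after"]


# ---------------------------------------------------------------------------
# cohort filter


def _profiles(n, org_idx=(), **kw):
    return pd.DataFrame(
        {
            "user_id": [f"u{i:03d}" for i in range(n)],
            "gender": "female",
            "age_group": "19_29",
            "race": "white",
            "is_org": [i in org_idx for i in range(n)],
            "follows": [[] for _ in range(n)],
            "hashtags": [[] for _ in range(n)],
        }
    )


def _period_table(user_ids, nb=3, na=2):
    df = pd.DataFrame(
        {
            "user_id": user_ids,
            "mean_before": 10.0,
            "mean_after": 5.0,
            "reduction": 5.0,
            "n_weeks_before": nb,
            "n_weeks_after": na,
            "n_posts": 30,
            "weekly_post_rate": 6.0,
        }
    ).set_index("user_id")
    return df


def test_filter_cohort_planted_violations_and_conservation():
    profiles = _profiles(100, org_idx=range(4))  # 4 organizations
    period = _period_table([f"u{i:03d}" for i in range(100)])
    # users 4..6 absent after; 7..9 absent before
    period.loc[[f"u{i:03d}" for i in (4, 5, 6)], "n_weeks_after"] = 0
    period.loc[[f"u{i:03d}" for i in (7, 8, 9)], "n_weeks_before"] = 0
    cohort, log = filter_cohort(profiles, period)
    assert len(cohort) == 90 and len(log) == 10
    assert len(cohort) + len(log) == len(profiles)
    reasons = log.set_index("user_id")["reason"]
    assert (reasons.loc[[f"u{i:03d}" for i in range(4)]] == "organization").all()
    assert (reasons.loc[["u004", "u005", "u006"]] == "absent_after").all()
    assert (reasons.loc[["u007", "u008", "u009"]] == "absent_before").all()


def test_filter_cohort_user_without_posts_logged():
    profiles = _profiles(3)
    period = _period_table(["u000", "u001"])
    cohort, log = filter_cohort(profiles, period)
    assert list(log["user_id"]) == ["u002"]
    assert list(log["reason"]) == ["no_posts"]


def test_filter_cohort_duplicate_ids_error():
    profiles = pd.concat([_profiles(2)] * 2, ignore_index=True)
    with pytest.raises(ValidationError):
        filter_cohort(profiles, _period_table(["u000", "u001"]))


# ---------------------------------------------------------------------------
# home location and density


def test_home_location_single_coordinate(toy_state_table):
    assign = box_state_assigner(toy_state_table)
    pt, state = home_location([(35.0, -105.0)] * 4, assign)
    assert (pt.lat, pt.lon) == pytest.approx((35.0, -105.0), abs=1e-9)
    assert state == "A"


def test_home_location_symmetric_posts(toy_state_table):
    assign = box_state_assigner(toy_state_table)
    pts = [(34.0, -95.0), (36.0, -95.0), (35.0, -94.0), (35.0, -96.0)]
    pt, state = home_location(pts, assign)
    # cos(lat) weighting shifts the spherical mean a few millidegrees
    assert (pt.lat, pt.lon) == pytest.approx((35.0, -95.0), abs=5e-3)
    assert state == "B"


def test_home_location_outside_all_states(toy_state_table):
    assign = box_state_assigner(toy_state_table)
    _, state = home_location([(10.0, 10.0)], assign)
    assert state == "unknown"


def test_density_median_tie_break():
    table = {"A": 10.0, "B": 20.0, "C": 30.0}
    assert density_category("B", table) == "low"  # at the median -> low
    assert density_category("C", table) == "high"
    assert density_category("A", table) == "low"
    with pytest.raises(ValidationError):
        density_category("Z", table)


def test_density_partition_matches_sort_based_oracle(rng):
    states = {f"S{i:02d}": float(v) for i, v in enumerate(rng.uniform(1, 500, 51))}
    cats = density_category_table(states)
    ranked = sorted(states.values())
    median = ranked[25]  # 51 entries -> middle of the sorted list
    for s, v in states.items():
        assert cats[s] == ("high" if v > median else "low")
    # permutation invariance of the table
    items = list(states.items())
    rng.shuffle(items)
    assert density_category_table(dict(items)) == cats


# ---------------------------------------------------------------------------
# labeling rules

DEM = {"speakerpelosi", "senschumer"}
REP = {"gopleader", "senatemajldr"}


@pytest.mark.parametrize(
    "follows, expected",
    [
        ({"speakerpelosi"}, "democrat"),
        ({"@SpeakerPelosi"}, "democrat"),
        ({"gopleader", "someoneelse"}, "republican"),
        (set(), "unknown"),
        ({"speakerpelosi", "gopleader"}, "unknown"),
    ],
)
def test_affiliation_from_follows(follows, expected):
    assert affiliation_from_follows(follows, DEM, REP) == expected


def test_affiliation_order_independent_and_idempotent(rng):
    follows = ["senschumer", "other1", "other2"]
    labels = {
        affiliation_from_follows(perm, DEM, REP)
        for perm in (follows, list(reversed(follows)), follows * 2)
    }
    assert labels == {"democrat"}


def test_affiliation_from_state():
    votes = {"A": "republican", "B": "democrat"}
    assert affiliation_from_state("B", votes) == "democrat"
    assert affiliation_from_state("unknown", votes) == "unknown"
    assert affiliation_from_state("Z", votes) == "unknown"


def test_trump_flag_and_affiliation_composition():
    # following only Trump: flag set, but affiliation stays unknown even if
    # the raw account lists contained the handle
    follows = {"realdonaldtrump"}
    dem = strip_trump_handle(DEM)
    rep = strip_trump_handle(REP | {"realdonaldtrump"})
    assert trump_follow_flag(follows) is True
    assert affiliation_from_follows(follows, dem, rep) == "unknown"
    assert trump_follow_flag(set()) is False


def test_hashtag_flags_planted_fixture(rng):
    target = {"covid19", "coronavirus"}
    users = [{f"tag{i}"} for i in range(50)]
    planted = rng.choice(50, size=12, replace=False)
    for i in planted:
        users[i] = users[i] | {"covid19"}
    flags = [hashtag_flag(u, target) for u in users]
    assert sum(flags) == 12
    assert all(flags[i] for i in planted)
    assert hashtag_flag({"anything"}, set()) is False
    assert hashtag_flag({"#COVID19"}, target) is True


@pytest.mark.parametrize(
    "age_group, expected",
    [
        ("under18", "under30"),
        ("19_29", "under30"),
        ("30_39", "over30"),
        ("over39", "over30"),
        ("unknown", "unknown"),
    ],
)
def test_bin_age(age_group, expected):
    assert bin_age(age_group) == expected


def test_bin_age_rejects_garbage():
    with pytest.raises(ValidationError):
        bin_age("40ish")


# ---------------------------------------------------------------------------
# trust / risk


def test_weighted_average_examples(rng):
    assert weighted_average([10, 20], [1, 1]) == 15.0
    assert weighted_average([7.5], [3.0]) == 7.5
    v, w = rng.uniform(0, 50, 5), rng.uniform(0.1, 3, 5)
    assert weighted_average(v, w) == pytest.approx(float(np.average(v, weights=w)))
    with pytest.raises(ValidationError):
        weighted_average([1, 2], [0, 0])


def test_attach_trust_and_risk_lookup(make_cohort_fn):
    cohort = make_cohort_fn(40)
    out = attach_trust_and_risk(
        cohort.drop(columns=["trust_age", "trust_race", "risk"]),
        trust_by_race={"white": 17.0, "black": 25.0, "asian": 28.0, "latinx": 26.0},
        trust_by_agebin={"under30": 19.0, "over30": 20.3},
        risk_by_state={"A": 1234.0},
    )
    assert (out.loc[out.age_bin == "under30", "trust_age"] == 19.0).all()
    assert (out.loc[out.age_bin == "over30", "trust_age"] == 20.3).all()
    assert (out["risk"] == 1234.0).all()
    assert (
        out["trust_race"]
        == out["race"].map({"white": 17.0, "black": 25.0, "asian": 28.0, "latinx": 26.0})
    ).all()


def test_attach_trust_missing_category_errors(make_cohort_fn):
    cohort = make_cohort_fn(10).drop(columns=["trust_age", "trust_race", "risk"])
    with pytest.raises(ValidationError):
        attach_trust_and_risk(
            cohort,
            trust_by_race={"white": 17.0},  # black/asian/latinx present but absent
            trust_by_agebin={"under30": 19.0, "over30": 20.3},
            risk_by_state={"A": 1.0},
        )
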