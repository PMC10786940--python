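"""Cohort construction: filters, labels and covariates.

Turns raw geotagged posts plus user attribute records and lookup tables into
the one-row-per-user analysis table.  A user enters the cohort only if they
have at least one geotagged week both before and after the cut date and are
not an organizational account; every excluded user is logged with a reason
code, so input users are conserved across cohort + exclusion log.

The dependent variable throughout is the *mobility reduction*: the user's
mean weekly mobility index over the before period minus the mean over the
after period, in km.  Positive values mean reduced movement.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geo import (
    GeoPoint,
    UserWeekMobility,
    ValidationError,
    spherical_centroid,
    week_monday,
)

__all__ = [
    "StudyWindow",
    "UserProfile",
    "period_means",
    "period_means_table",
    "filter_cohort",
    "home_location",
    "density_category",
    "density_category_table",
    "affiliation_from_follows",
    "affiliation_from_state",
    "trump_follow_flag",
    "hashtag_flag",
    "bin_age",
    "weighted_average",
    "attach_trust_and_risk",
    "box_state_assigner",
    "build_cohort",
]

GENDERS = ("female", "male", "unknown")
AGE_GROUPS = ("under18", "19_29", "30_39", "over39", "unknown")
RACES = ("white", "black", "asian", "latinx", "unknown")
AFFILIATIONS = ("democrat", "republican", "unknown")

#: handle of the account flagged separately and excluded from party lists
TRUMP_HANDLE = "realdonaldtrump"


@dataclasses.dataclass(frozen=True)
class StudyWindow:
    """Study period split at the social-distancing cut date.

    Defaults follow the national "Slow the Spread" announcement: before =
    2019-01-01..2020-03-15, after = 2020-03-16..2020-06-21.
    """

    start: _dt.date = _dt.date(2019, 1, 1)
    cut: _dt.date = _dt.date(2020, 3, 16)
    end: _dt.date = _dt.date(2020, 6, 21)

    def __post_init__(self):
        if not (self.start < self.cut <= self.end):
            raise ValidationError(
                f"invalid study window: need start < cut <= end, got "
                f"{self.start} / {self.cut} / {self.end}"
            )


@dataclasses.dataclass(frozen=True)
class UserProfile:
    """Attribute record for one user; labels are consumed, never inferred."""

    user_id: str
    gender: str = "unknown"
    age_group: str = "unknown"
    race: str = "unknown"
    is_org: bool = False
    followed_handles: frozenset = frozenset()
    hashtags_used: frozenset = frozenset()

    def __post_init__(self):
        for field, allowed in (
            ("gender", GENDERS),
            ("age_group", AGE_GROUPS),
            ("race", RACES),
        ):
            if getattr(self, field) not in allowed:
                raise ValidationError(
                    f"{field}={getattr(self, field)!r} not in {allowed}"
                )
        object.__setattr__(
            self,
            "followed_handles",
            frozenset(normalize_handle(h) for h in self.followed_handles),
        )
        object.__setattr__(
            self,
            "hashtags_used",
            frozenset(normalize_hashtag(h) for h in self.hashtags_used),
        )


def normalize_handle(handle: str) -> str:
    return handle.lstrip("@").strip().lower()


def normalize_hashtag(tag: str) -> str:
    return tag.lstrip("#").strip().lower()


# ---------------------------------------------------------------------------
# period means


def _week_is_after(iso_year: int, iso_week: int, cut: _dt.date) -> bool:
    # a week belongs to "after" iff its Monday falls on/after the cut
    return week_monday(iso_year, iso_week) >= cut


def _n_weeks(first: _dt.date, last: _dt.date) -> int:
    """Number of ISO weeks whose Monday lies in [first, last)."""
    first_monday = first + _dt.timedelta(days=(7 - first.weekday()) % 7)
    if first_monday >= last:
        return 0
    return (last - first_monday).days // 7 + 1


def period_means(
    series: Sequence[UserWeekMobility],
    window: StudyWindow,
    *,
    include_empty_weeks_as_zero: bool = False,
) -> tuple[float, float, float]:
    """Mean weekly index before and after the cut, and their difference.

    Weeks are weighted equally regardless of post count.  A period with no
    contributing weeks yields NaN means (the user is then excluded upstream).
    With ``include_empty_weeks_as_zero`` the mean is instead taken over every
    calendar week of the period, counting unobserved weeks as 0 km.
    """
    before, after = [], []
    for w in series:
        monday = week_monday(w.iso_year, w.iso_week)
        (after if monday >= window.cut else before).append(w.index_km)
    if include_empty_weeks_as_zero:
        nb = _n_weeks(window.start, window.cut)
        na = _n_weeks(window.cut, window.end + _dt.timedelta(days=1))
        mean_before = sum(before) / nb if nb and before else (0.0 if nb else math.nan)
        mean_after = sum(after) / na if na and after else (0.0 if na else math.nan)
        if not before:
            mean_before = math.nan
        if not after:
            mean_after = math.nan
    else:
        mean_before = sum(before) / len(before) if before else math.nan
        mean_after = sum(after) / len(after) if after else math.nan
    return mean_before, mean_after, mean_before - mean_after


def period_means_table(
    weekly: pd.DataFrame,
    window: StudyWindow,
    *,
    include_empty_weeks_as_zero: bool = False,
) -> pd.DataFrame:
    """Vectorised per-user period means over a weekly mobility table.

    Returns one row per user: ``mean_before, mean_after, reduction,
    n_weeks_before, n_weeks_after, n_posts, weekly_post_rate`` (posts per
    observed week).  Users missing a period keep NaN means.
    """
    if weekly.empty:
        return pd.DataFrame(
            columns=[
                "user_id",
                "mean_before",
                "mean_after",
                "reduction",
                "n_weeks_before",
                "n_weeks_after",
                "n_posts",
                "weekly_post_rate",
            ]
        ).set_index("user_id")
    mondays = np.array(
        [
            week_monday(y, w)
            for y, w in zip(weekly["iso_year"], weekly["iso_week"])
        ]
    )
    is_after = mondays >= window.cut
    df = weekly[["user_id", "n_posts", "index_km"]].copy()
    df["is_after"] = is_after
    g = df.groupby(["user_id", "is_after"], observed=True)["index_km"].agg(
        ["sum", "count"]
    )
    wide = g.unstack("is_after", fill_value=0.0)
    nb = wide.get(("count", False), pd.Series(0.0, index=wide.index))
    na = wide.get(("count", True), pd.Series(0.0, index=wide.index))
    sb = wide.get(("sum", False), pd.Series(0.0, index=wide.index))
    sa = wide.get(("sum", True), pd.Series(0.0, index=wide.index))
    if include_empty_weeks_as_zero:
        denom_b = float(_n_weeks(window.start, window.cut))
        denom_a = float(_n_weeks(window.cut, window.end + _dt.timedelta(days=1)))
    else:
        denom_b, denom_a = nb, na
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_before = np.where(nb > 0, sb / denom_b, np.nan)
        mean_after = np.where(na > 0, sa / denom_a, np.nan)
    posts = df.groupby("user_id", observed=True)["n_posts"].sum()
    out = pd.DataFrame(
        {
            "mean_before": mean_before,
            "mean_after": mean_after,
            "reduction": mean_before - mean_after,
            "n_weeks_before": nb.astype(int),
            "n_weeks_after": na.astype(int),
            "n_posts": posts.reindex(wide.index).astype(int),
        },
        index=wide.index,
    )
    out["weekly_post_rate"] = out["n_posts"] / (
        out["n_weeks_before"] + out["n_weeks_after"]
    )
    out.index.name = "user_id"
    return out


# ---------------------------------------------------------------------------
# filters


def filter_cohort(
    profiles: pd.DataFrame,
    period_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort filters; conserve every input user.

    Keeps users with at least one geotagged week in each period and
    ``is_org == False``.  Returns ``(cohort, exclusion_log)`` where the log
    has columns ``user_id, reason`` with reason codes ``organization``,
    ``absent_before``, ``absent_after``, ``no_posts``.
    """
    if profiles["user_id"].duplicated().any():
        dupes = profiles.loc[profiles["user_id"].duplicated(), "user_id"]
        raise ValidationError(f"duplicate user_ids: {sorted(set(dupes))[:5]}")
    merged = profiles.merge(
        period_table.reset_index(), on="user_id", how="left"
    )
    no_posts = merged["n_posts"].isna()
    absent_before = (~no_posts) & (merged["n_weeks_before"] == 0)
    absent_after = (~no_posts) & (merged["n_weeks_after"] == 0)
    org = merged["is_org"].astype(bool)

    reason = pd.Series(pd.NA, index=merged.index, dtype="object")
    # precedence: organization first (matches the collection pipeline order)
    reason[absent_after] = "absent_after"
    reason[absent_before] = "absent_before"
    reason[no_posts] = "no_posts"
    reason[org] = "organization"

    excluded = reason.notna()
    log = pd.DataFrame(
        {"user_id": merged.loc[excluded, "user_id"], "reason": reason[excluded]}
    ).reset_index(drop=True)
    cohort = merged.loc[~excluded].reset_index(drop=True)
    assert len(cohort) + len(log) == len(profiles)
    return cohort, log


# ---------------------------------------------------------------------------
# home location and density


def box_state_assigner(state_table: pd.DataFrame) -> Callable:
    """Point-to-state function from axis-aligned bounding boxes.

    ``state_table`` needs columns ``state, lat_min, lat_max, lon_min,
    lon_max``.  Returns a vectorised callable mapping (lat, lon) arrays to a
    state-name object array, ``"unknown"`` where no box contains the point.
    First matching row wins for overlapping boxes.
    """
    states = state_table["state"].to_numpy()
    lat_min = state_table["lat_min"].to_numpy(dtype=float)
    lat_max = state_table["lat_max"].to_numpy(dtype=float)
    lon_min = state_table["lon_min"].to_numpy(dtype=float)
    lon_max = state_table["lon_max"].to_numpy(dtype=float)

    def assign(lat, lon):
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        out = np.full(lat.shape, "unknown", dtype=object)
        unresolved = np.ones(lat.shape, dtype=bool)
        for i in range(len(states)):
            hit = (
                unresolved
                & (lat >= lat_min[i])
                & (lat <= lat_max[i])
                & (lon >= lon_min[i])
                & (lon <= lon_max[i])
            )
            out[hit] = states[i]
            unresolved &= ~hit
        return out

    return assign


def home_location(
    points: Sequence, state_of: Callable
) -> tuple[GeoPoint, str]:
    """Home point and state of one user.

    The home point is the spherical centroid of *all* of the user's
    geotagged posts in the window; the state is whatever the configured
    point-to-state function assigns to that centroid (``"unknown"`` outside
    every configured state).
    """
    centroid = spherical_centroid(points)
    state = str(state_of(centroid.lat, centroid.lon)[0])
    return centroid, state


def density_category(state: str, density_table: Mapping[str, float]) -> str:
    """``high`` iff the state's density strictly exceeds the median density.

    The median is taken over all table values; states at or below the median
    (including the median state itself for odd tables) are ``low``.
    """
    if state not in density_table:
        raise ValidationError(f"state {state!r} not in density table")
    med = float(np.median(list(density_table.values())))
    return "high" if float(density_table[state]) > med else "low"


def density_category_table(density_table: Mapping[str, float]) -> dict[str, str]:
    med = float(np.median(list(density_table.values())))
    return {
        s: ("high" if float(v) > med else "low")
        for s, v in density_table.items()
    }


# ---------------------------------------------------------------------------
# labeling rules


def affiliation_from_follows(
    followed: Iterable[str], dem_accounts: Iterable[str], rep_accounts: Iterable[str]
) -> str:
    """Party label from followed accounts.

    ``democrat`` if the user follows at least one Democratic account and no
    Republican one; symmetric for ``republican``; ``unknown`` if neither or
    both (following both parties is deliberately uninformative).
    """
    followed = {normalize_handle(h) for h in followed}
    dem = bool(followed & {normalize_handle(h) for h in dem_accounts})
    rep = bool(followed & {normalize_handle(h) for h in rep_accounts})
    if dem and not rep:
        return "democrat"
    if rep and not dem:
        return "republican"
    return "unknown"


def affiliation_from_state(
    home_state: str, vote_table: Mapping[str, str]
) -> str:
    """Party label from the home state's 2016 presidential vote."""
    if home_state == "unknown" or home_state not in vote_table:
        return "unknown"
    label = str(vote_table[home_state])
    if label not in ("democrat", "republican"):
        raise ValidationError(f"bad vote table entry {label!r}")
    return label


def trump_follow_flag(
    followed: Iterable[str], trump_handle: str = TRUMP_HANDLE
) -> bool:
    """Whether the user follows the configured Trump handle.

    The handle is tracked as a separate field and must be removed from both
    party account lists before follow-based labeling (see
    :func:`strip_trump_handle`).
    """
    return normalize_handle(trump_handle) in {
        normalize_handle(h) for h in followed
    }


def strip_trump_handle(
    accounts: Iterable[str], trump_handle: str = TRUMP_HANDLE
) -> set[str]:
    t = normalize_handle(trump_handle)
    return {normalize_handle(h) for h in accounts} - {t}


def hashtag_flag(hashtags_used: Iterable[str], target_list: Iterable[str]) -> bool:
    """True iff the user used any hashtag from the target list."""
    used = {normalize_hashtag(h) for h in hashtags_used}
    return bool(used & {normalize_hashtag(h) for h in target_list})


_AGE_BIN = {
    "under18": "under30",
    "19_29": "under30",
    "30_39": "over30",
    "over39": "over30",
    "unknown": "unknown",
}


def bin_age(age_group: str) -> str:
    """Collapse the four age categories to over/under 30.

    ``unknown`` stays ``unknown`` and is dropped listwise from analyses
    stratified on age.
    """
    try:
        return _AGE_BIN[age_group]
    except KeyError:
        raise ValidationError(f"unknown age group {age_group!r}") from None


def weighted_average(values: Sequence[float], weights: Sequence[float]) -> float:
    """Population-weighted average, used to collapse survey trust scores."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValidationError("values and weights differ in length")
    if np.any(weights < 0):
        raise ValidationError("negative weight")
    total = weights.sum()
    if total <= 0:
        raise ValidationError("zero total weight")
    return float(np.dot(values, weights) / total)


def attach_trust_and_risk(
    cohort: pd.DataFrame,
    trust_by_race: Mapping[str, float],
    trust_by_agebin: Mapping[str, float],
    risk_by_state: Mapping[str, float],
) -> pd.DataFrame:
    """Attach group-level trust scores and state-level perceived risk.

    Adds ``trust_race`` (by race/ethnicity), ``trust_age`` (by age bin) and
    ``risk`` (cumulative confirmed cases of the home state at the window
    end).  Unknown categories yield NaN and are dropped listwise by any
    analysis using the column; a *known* category missing from its map is an
    error.
    """
    out = cohort.copy()
    for col, mapping, name in (
        ("race", trust_by_race, "trust_race"),
        ("age_bin", trust_by_agebin, "trust_age"),
        ("home_state", risk_by_state, "risk"),
    ):
        present = set(out[col].unique()) - {"unknown"}
        missing = present - set(mapping)
        if missing:
            raise ValidationError(
                f"no {name} entry for {sorted(missing)} in column {col!r}"
            )
        out[name] = out[col].map(
            {**{k: float(v) for k, v in mapping.items()}, "unknown": np.nan}
        )
    return out


# ---------------------------------------------------------------------------
# orchestration


def build_cohort(
    profiles: pd.DataFrame,
    weekly: pd.DataFrame,
    posts: pd.DataFrame,
    *,
    window: StudyWindow,
    state_table: pd.DataFrame,
    dem_accounts: Iterable[str],
    rep_accounts: Iterable[str],
    covid_hashtags: Iterable[str],
    distancing_hashtags: Iterable[str],
    trust_by_race: Mapping[str, float],
    trust_by_agebin: Mapping[str, float],
    affiliation_method: str = "congress",
    trump_handle: str = TRUMP_HANDLE,
    include_empty_weeks_as_zero: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the analysis cohort.

    Parameters
    ----------
    profiles
        One row per user: ``user_id, gender, age_group, race, is_org,
        follows, hashtags`` (the last two hold lists/sets of strings).
    weekly
        Weekly mobility table from :func:`socmob.geo.weekly_mobility_table`.
    posts
        The raw posts table (needed for the home centroid).
    state_table
        ``state, lat_min, lat_max, lon_min, lon_max, density_per_km2,
        vote2016, cum_cases``.
    affiliation_method
        ``leadership`` | ``congress`` | ``state_vote``.  ``congress`` is the
        default used in the main analysis; for follow-based methods the
        account lists are stripped of the Trump handle first.

    Returns
    -------
    (cohort, exclusion_log) — conservation holds: every input user appears
    in exactly one of the two.
    """
    if affiliation_method not in ("leadership", "congress", "state_vote"):
        raise ValidationError(
            f"unknown affiliation method {affiliation_method!r}"
        )
    period = period_means_table(
        weekly, window, include_empty_weeks_as_zero=include_empty_weeks_as_zero
    )
    cohort, log = filter_cohort(profiles, period)
    if cohort.empty:
        return cohort, log

    # home centroid over all of the user's posts
    kept = set(cohort["user_id"])
    posts_kept = posts[posts["user_id"].isin(kept)]
    from .geo import _unit_vectors, _vectors_to_latlon  # reuse internals

    x, y, z = _unit_vectors(
        posts_kept["lat"].to_numpy(dtype=float),
        posts_kept["lon"].to_numpy(dtype=float),
    )
    hv = pd.DataFrame({"user_id": posts_kept["user_id"], "x": x, "y": y, "z": z})
    hm = hv.groupby("user_id", observed=True).mean()
    hlat, hlon = _vectors_to_latlon(
        hm["x"].to_numpy(), hm["y"].to_numpy(), hm["z"].to_numpy()
    )
    homes = pd.DataFrame(
        {"home_lat": hlat, "home_lon": hlon}, index=hm.index
    )
    cohort = cohort.merge(homes, left_on="user_id", right_index=True, how="left")

    assign = box_state_assigner(state_table)
    cohort["home_state"] = assign(
        cohort["home_lat"].to_numpy(), cohort["home_lon"].to_numpy()
    )

    density_map = dict(
        zip(state_table["state"], state_table["density_per_km2"])
    )
    cat_map = density_category_table(density_map)
    cohort["density"] = cohort["home_state"].map(density_map)
    cohort["density_cat"] = cohort["home_state"].map(cat_map).fillna("unknown")

    dem = strip_trump_handle(dem_accounts, trump_handle)
    rep = strip_trump_handle(rep_accounts, trump_handle)
    vote_map = dict(zip(state_table["state"], state_table["vote2016"]))
    if affiliation_method == "state_vote":
        cohort["affiliation"] = [
            affiliation_from_state(s, vote_map) for s in cohort["home_state"]
        ]
    else:
        cohort["affiliation"] = [
            affiliation_from_follows(f, dem, rep) for f in cohort["follows"]
        ]
    cohort["follows_trump"] = [
        trump_follow_flag(f, trump_handle) for f in cohort["follows"]
    ]
    cohort["covid_hashtag"] = [
        hashtag_flag(h, covid_hashtags) for h in cohort["hashtags"]
    ]
    cohort["distancing_hashtag"] = [
        hashtag_flag(h, distancing_hashtags) for h in cohort["hashtags"]
    ]
    cohort["age_bin"] = cohort["age_group"].map(bin_age)

    risk_map = dict(zip(state_table["state"], state_table["cum_cases"]))
    cohort = attach_trust_and_risk(
        cohort, trust_by_race, trust_by_agebin, risk_map
    )
    cols = [
        "user_id",
        "mean_before",
        "mean_after",
        "reduction",
        "gender",
        "age_group",
        "age_bin",
        "race",
        "affiliation",
        "follows_trump",
        "home_state",
        "home_lat",
        "home_lon",
        "density",
        "density_cat",
        "covid_hashtag",
        "distancing_hashtag",
        "trust_race",
        "trust_age",
        "risk",
        "n_weeks_before",
        "n_weeks_after",
        "n_posts",
        "weekly_post_rate",
    ]
    return cohort[cols], log
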