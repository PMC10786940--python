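"""Synthetic geotagged post streams with planted group effects.

The generator emulates the statistical structure the analysis assumes: each
user has a home point inside a toy state, a persistent dispersion scale
``sigma_before`` (lognormal across users), and a planted *fractional
reduction* of that scale after the social-distancing cut date.  The
fraction is a shared baseline plus additive contributions from the user's
attribute levels, so group differences in realised mobility reduction are
known by construction and serve as the recovery oracle for the ANOVA and
regression stages.

Post model, per user-week: the week is active with probability
``p_active_week``; if active the post count is ``1 + Poisson(rate - 1)``
(mean ``weekly_post_rate``); each post sits at the home point plus a
displacement with half-normal radial distance ``|N(0, sigma_w)|`` and
uniform bearing in the local tangent plane, where::

    sigma_w = sigma_before * (1 - planted_fraction * 1[week >= cut])
              * exp(N(0, noise_sd))

Because the weekly mobility index is scale-equivariant in sigma, the
expected index after the cut is ``(1 - planted_fraction)`` times the
expected index before it.

State geometry is a set of axis-aligned lat/lon boxes, so point-in-state is
exact and dependency-free.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import StudyWindow
from .geo import EARTH_RADIUS_KM, ValidationError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_state_table",
    "sample_users",
    "sample_posts",
    "expected_group_reduction",
    "simulate_dataset",
    "TRUST_BY_AGEBIN",
    "TRUST_BY_RACE",
]

#: population-weighted trust-in-government scores by age bin (survey-derived)
TRUST_BY_AGEBIN = {"under30": 19.0, "over30": 20.3}
#: synthetic stand-in trust scores by race/ethnicity (no public per-group
#: values are bundled; shape mirrors the higher trust among non-white groups)
TRUST_BY_RACE = {"white": 17.0, "black": 25.0, "asian": 28.0, "latinx": 26.0}

DEM_LEADERSHIP = ("speakerpelosi", "senschumer")
REP_LEADERSHIP = ("gopleader", "senatemajldr")
#: toy "all members of Congress" lists: leadership plus backbench handles
DEM_CONGRESS = DEM_LEADERSHIP + ("repblue01", "repblue02", "senblue01")
REP_CONGRESS = REP_LEADERSHIP + ("repred01", "repred02", "senred01")

COVID_HASHTAGS = ("covid19", "coronavirus", "covid_19", "pandemic")
DISTANCING_HASHTAGS = ("socialdistancing", "stayhome", "quarantinelife")


def default_state_table() -> pd.DataFrame:
    """Ten toy states on a 5x2 grid of 6°x5° boxes.

    Densities straddle their median so both density categories are
    populated; votes and cumulative case counts are synthetic but follow the
    usual density gradient (denser states: more cases, more Democratic).
    """
    rows = []
    densities = [10, 25, 40, 60, 85, 110, 150, 220, 320, 450]
    votes = [
        "republican",
        "republican",
        "republican",
        "republican",
        "republican",
        "democrat",
        "republican",
        "democrat",
        "democrat",
        "democrat",
    ]
    cases = [3000, 6000, 9000, 15000, 22000, 35000, 52000, 90000, 160000, 280000]
    # user share per state: concentrated in the denser states
    weights = [0.03, 0.04, 0.05, 0.06, 0.08, 0.09, 0.16, 0.155, 0.155, 0.18]
    for i in range(10):
        col, row = i % 5, i // 5
        lon0 = -125.0 + 6.0 * col
        lat0 = 33.0 + 5.0 * row
        rows.append(
            {
                "state": f"S{i:02d}",
                "lat_min": lat0,
                "lat_max": lat0 + 5.0,
                "lon_min": lon0,
                "lon_max": lon0 + 6.0,
                "density_per_km2": densities[i],
                "vote2016": votes[i],
                "cum_cases": cases[i],
                "weight": weights[i],
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions.

    ``effects`` maps attribute -> level -> additive fractional reduction;
    per-user ``planted_fraction = clip(base_effect + sum(levels), 0, 0.95)``.
    Default effect steps of 0.05 mirror the qualitative orderings of the
    findings being emulated (male > female, over-30 > under-30,
    Asian > Latinx > White > Black, Democrat > Republican > unknown,
    high-density > low-density states).
    """

    n_users: int = 2000
    seed: int = 0
    window: StudyWindow = dataclasses.field(default_factory=StudyWindow)
    state_table: pd.DataFrame = dataclasses.field(
        default_factory=default_state_table
    )
    gender_marginals: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"female": 0.425, "male": 0.565, "unknown": 0.01}
    )
    age_marginals: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "under18": 0.06,
            "19_29": 0.48,
            "30_39": 0.25,
            "over39": 0.20,
            "unknown": 0.01,
        }
    )
    race_marginals: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "white": 0.40,
            "black": 0.32,
            "asian": 0.09,
            "latinx": 0.18,
            "unknown": 0.01,
        }
    )
    affiliation_marginals: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "unknown": 0.80,
            "democrat": 0.14,
            "republican": 0.06,
        }
    )
    p_org: float = 0.10
    p_follows_trump: float = 0.10
    p_covid_hashtag: float = 0.30
    p_distancing_hashtag: float = 0.08
    weekly_post_rate: float = 14.25
    p_active_week: float = 0.5
    sigma_log_median_km: float = 25.0
    sigma_log_sd: float = 0.8
    noise_sd: float = 0.6
    base_effect: float = 0.15
    effects: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: {
            "gender": {"male": 0.05},
            "age_bin": {"over30": 0.05},
            "race": {"black": 0.0, "white": 0.05, "latinx": 0.10, "asian": 0.15},
            "affiliation": {"republican": 0.05, "democrat": 0.10},
            "density_cat": {"high": 0.05},
        }
    )
    dem_accounts: tuple = DEM_CONGRESS
    rep_accounts: tuple = REP_CONGRESS
    trump_handle: str = "realdonaldtrump"
    covid_hashtags: tuple = COVID_HASHTAGS
    distancing_hashtags: tuple = DISTANCING_HASHTAGS

    def __post_init__(self):
        for name in ("gender", "age", "race", "affiliation"):
            m = getattr(self, f"{name}_marginals")
            if any(p < 0 or p > 1 for p in m.values()) or abs(
                sum(m.values()) - 1.0
            ) > 1e-9:
                raise ValidationError(f"{name} marginals must sum to 1")
        for attr, levels in self.effects.items():
            for level, e in levels.items():
                if not (0.0 <= e < 1.0):
                    raise ValidationError(
                        f"effect {attr}:{level}={e} outside [0, 1)"
                    )


@dataclasses.dataclass
class GroundTruth:
    """Per-user generative parameters; the oracle for recovery tests."""

    users: pd.DataFrame  # user_id, attrs, home, state, sigma_before, planted_fraction
    config: SyntheticConfig

    def expected_group_reduction(
        self, attribute: str, level: str, include_orgs: bool = False
    ) -> float:
        return expected_group_reduction(
            self, attribute, level, include_orgs=include_orgs
        )

    def group_order(self, attribute: str, include_orgs: bool = False):
        """Levels sorted by descending expected planted reduction."""
        df = self.users if include_orgs else self.users[~self.users["is_org"]]
        means = df.groupby(attribute, observed=True)["planted_fraction"].mean()
        return list(means.sort_values(ascending=False).index)


def _draw_categorical(rng, marginals: Mapping[str, float], n: int):
    levels = list(marginals)
    p = np.array([marginals[l] for l in levels], dtype=float)
    return np.array(levels, dtype=object)[rng.choice(len(levels), size=n, p=p)]


def sample_users(config: SyntheticConfig, seed: int | None = None):
    """Draw user profiles and their generative ground truth.

    Attributes are drawn independently from the marginals; the home state
    is drawn from the state weights and the home point uniformly within the
    state's box.  Follow sets are constructed consistently with the drawn
    affiliation (Democrats follow a Democratic leadership handle, etc.), so
    follow-based labeling round-trips.

    Returns ``(profiles, ground_truth)``; profiles is the user-attribute
    table consumed by the cohort builder (follows/hashtags as lists).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_users
    user_id = np.array([f"u{i:07d}" for i in range(n)], dtype=object)
    gender = _draw_categorical(rng, config.gender_marginals, n)
    age_group = _draw_categorical(rng, config.age_marginals, n)
    race = _draw_categorical(rng, config.race_marginals, n)
    affiliation = _draw_categorical(rng, config.affiliation_marginals, n)
    is_org = rng.random(n) < config.p_org
    follows_trump = rng.random(n) < config.p_follows_trump

    st = config.state_table
    w = st["weight"].to_numpy(dtype=float)
    state_idx = rng.choice(len(st), size=n, p=w / w.sum())
    lat0 = st["lat_min"].to_numpy()[state_idx]
    lat1 = st["lat_max"].to_numpy()[state_idx]
    lon0 = st["lon_min"].to_numpy()[state_idx]
    lon1 = st["lon_max"].to_numpy()[state_idx]
    # margin keeps centroid drift from leaking into the neighbouring box
    home_lat = lat0 + (0.1 + 0.8 * rng.random(n)) * (lat1 - lat0)
    home_lon = lon0 + (0.1 + 0.8 * rng.random(n)) * (lon1 - lon0)
    state = st["state"].to_numpy(dtype=object)[state_idx]

    from .cohort import bin_age, density_category_table

    density_map = dict(zip(st["state"], st["density_per_km2"]))
    cat_map = density_category_table(density_map)
    density_cat = np.array([cat_map[s] for s in state], dtype=object)
    age_bin = np.array([bin_age(a) for a in age_group], dtype=object)

    frac = np.full(n, config.base_effect, dtype=float)
    attr_values = {
        "gender": gender,
        "age_bin": age_bin,
        "race": race,
        "affiliation": affiliation,
        "density_cat": density_cat,
    }
    for attr, levels in config.effects.items():
        if attr not in attr_values:
            raise ValidationError(f"effects refer to unknown attribute {attr!r}")
        vals = attr_values[attr]
        for level, e in levels.items():
            frac[vals == level] += e
    frac = np.clip(frac, 0.0, 0.95)

    sigma_before = np.exp(
        np.log(config.sigma_log_median_km)
        + config.sigma_log_sd * rng.standard_normal(n)
    )

    dem_pick = rng.integers(0, len(DEM_LEADERSHIP), size=n)
    rep_pick = rng.integers(0, len(REP_LEADERSHIP), size=n)
    follows = []
    for i in range(n):
        f = set()
        if affiliation[i] == "democrat":
            f.add(DEM_LEADERSHIP[dem_pick[i]])
        elif affiliation[i] == "republican":
            f.add(REP_LEADERSHIP[rep_pick[i]])
        if follows_trump[i]:
            f.add(config.trump_handle)
        follows.append(sorted(f))

    has_covid = rng.random(n) < config.p_covid_hashtag
    has_dist = rng.random(n) < config.p_distancing_hashtag
    tag_pick = rng.integers(0, len(config.covid_hashtags), size=n)
    dtag_pick = rng.integers(0, len(config.distancing_hashtags), size=n)
    hashtags = []
    for i in range(n):
        h = {"weekendvibes"}  # every user has some unrelated tag
        if has_covid[i]:
            h.add(config.covid_hashtags[tag_pick[i]])
        if has_dist[i]:
            h.add(config.distancing_hashtags[dtag_pick[i]])
        hashtags.append(sorted(h))

    profiles = pd.DataFrame(
        {
            "user_id": user_id,
            "gender": gender,
            "age_group": age_group,
            "race": race,
            "is_org": is_org,
            "follows": follows,
            "hashtags": hashtags,
        }
    )
    users = pd.DataFrame(
        {
            "user_id": user_id,
            "gender": gender,
            "age_group": age_group,
            "age_bin": age_bin,
            "race": race,
            "affiliation": affiliation,
            "is_org": is_org,
            "follows_trump": follows_trump,
            "state": state,
            "density_cat": density_cat,
            "home_lat": home_lat,
            "home_lon": home_lon,
            "sigma_before": sigma_before,
            "planted_fraction": frac,
        }
    )
    return profiles, GroundTruth(users=users, config=config)


def _study_weeks(window: StudyWindow):
    """Mondays, interval starts and lengths (s) of weeks touching the window."""
    mondays = []
    d = window.start - _dt.timedelta(days=window.start.weekday())
    while d <= window.end:
        mondays.append(d)
        d += _dt.timedelta(days=7)
    starts, lengths = [], []
    for m in mondays:
        a = max(m, window.start)
        b = min(m + _dt.timedelta(days=7), window.end + _dt.timedelta(days=1))
        starts.append(_dt.datetime(a.year, a.month, a.day, tzinfo=_dt.timezone.utc))
        lengths.append((b - a).days * 86400)
    return mondays, starts, lengths


def sample_posts(
    profiles: pd.DataFrame,
    ground_truth: GroundTruth,
    config: SyntheticConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate the geotagged post stream for the sampled users.

    Fully vectorised; returns a DataFrame with ``user_id`` (categorical),
    ``ts`` (tz-aware datetime64), ``lat``, ``lon``, in user-week order.
    Displacements that would cross a pole or the date line are redrawn by
    rejection (they cannot occur with the default mid-latitude states, but
    the guard is counted in ``posts.attrs["n_redrawn"]``).
    """
    rng = np.random.default_rng(
        (config.seed + 1) if seed is None else seed
    )
    gt = ground_truth.users
    n_users = len(gt)
    mondays, week_starts, week_lengths = _study_weeks(config.window)
    n_weeks = len(mondays)
    is_after = np.array([m >= config.window.cut for m in mondays])

    active = rng.random((n_users, n_weeks)) < config.p_active_week
    u_idx, w_idx = np.nonzero(active)
    lam = max(config.weekly_post_rate - 1.0, 0.0)
    counts = 1 + rng.poisson(lam, size=u_idx.size)

    sigma_b = gt["sigma_before"].to_numpy()
    frac = gt["planted_fraction"].to_numpy()
    sigma_w = (
        sigma_b[u_idx]
        * (1.0 - frac[u_idx] * is_after[w_idx])
        * np.exp(config.noise_sd * rng.standard_normal(u_idx.size))
    )

    post_user = np.repeat(u_idx, counts)
    post_week = np.repeat(w_idx, counts)
    post_sigma = np.repeat(sigma_w, counts)
    n_posts = post_user.size

    home_lat = gt["home_lat"].to_numpy()[post_user]
    home_lon = gt["home_lon"].to_numpy()[post_user]
    deg = 180.0 / np.pi
    lat = np.empty(n_posts)
    lon = np.empty(n_posts)
    todo = np.arange(n_posts)
    n_redrawn = 0
    for _ in range(20):
        r = np.abs(rng.standard_normal(todo.size)) * post_sigma[todo]
        theta = rng.uniform(0.0, 2.0 * np.pi, size=todo.size)
        dlat = (r / EARTH_RADIUS_KM) * deg * np.cos(theta)
        dlon = (
            (r / (EARTH_RADIUS_KM * np.cos(np.deg2rad(home_lat[todo]))))
            * deg
            * np.sin(theta)
        )
        lat[todo] = home_lat[todo] + dlat
        lon[todo] = home_lon[todo] + dlon
        bad = (
            (np.abs(lat[todo]) > 89.0)
            | (lon[todo] <= -180.0)
            | (lon[todo] > 180.0)
        )
        if not bad.any():
            break
        todo = todo[bad]
        n_redrawn += todo.size
    else:
        raise ValidationError("displacement rejection did not terminate")

    starts_s = np.array(
        [int(s.timestamp()) for s in week_starts], dtype=np.int64
    )
    lengths_s = np.array(week_lengths, dtype=np.int64)
    ts_s = starts_s[post_week] + (
        rng.random(n_posts) * lengths_s[post_week]
    ).astype(np.int64)

    posts = pd.DataFrame(
        {
            "user_id": pd.Categorical.from_codes(
                post_user.astype(np.int32), categories=gt["user_id"]
            ),
            "ts": pd.to_datetime(ts_s, unit="s", utc=True),
            "lat": lat,
            "lon": lon,
        }
    )
    posts.attrs["n_redrawn"] = n_redrawn
    return posts


def expected_group_reduction(
    ground_truth: GroundTruth,
    attribute: str,
    level: str,
    include_orgs: bool = False,
) -> float:
    """Mean planted fractional reduction over the users in one group."""
    df = ground_truth.users
    if not include_orgs:
        df = df[~df["is_org"]]
    if attribute not in df.columns:
        raise ValidationError(f"unknown attribute {attribute!r}")
    grp = df.loc[df[attribute] == level, "planted_fraction"]
    if grp.empty:
        raise ValidationError(f"empty group {attribute}={level}")
    return float(grp.mean())


def simulate_dataset(config: SyntheticConfig, seed: int | None = None):
    """Profiles, posts and ground truth in one call.

    ``seed`` overrides ``config.seed``; user and post streams use distinct
    child seeds so the two stages stay independently reproducible.
    """
    base = config.seed if seed is None else seed
    profiles, gt = sample_users(config, seed=base)
    posts = sample_posts(profiles, gt, config, seed=base + 1)
    return profiles, posts, gt
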