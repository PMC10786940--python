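import datetime as dt

import numpy as np
import pandas as pd
import pytest

from socmob.cohort import StudyWindow


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def window():
    return StudyWindow()


@pytest.fixture
def toy_state_table():
    """Three box states side by side on the equator-ish band."""
    return pd.DataFrame(
        {
            "state": ["A", "B", "C"],
            "lat_min": [30.0, 30.0, 30.0],
            "lat_max": [40.0, 40.0, 40.0],
            "lon_min": [-110.0, -100.0, -90.0],
            "lon_max": [-100.1, -90.1, -80.1],
            "density_per_km2": [10.0, 20.0, 30.0],
            "vote2016": ["republican", "democrat", "democrat"],
            "cum_cases": [1000, 2000, 3000],
            "weight": [0.3, 0.3, 0.4],
        }
    )


def make_cohort(
    n: int,
    rng: np.random.Generator,
    *,
    reduction=None,
    gender=None,
    age_bin=None,
    race=None,
    affiliation=None,
    density_cat=None,
) -> pd.DataFrame:
    """Cohort-level synthetic table for unit tests of the statistics layer.

    Columns default to balanced random draws; pass arrays to plant
    structure.  mean_before/mean_after are derived so that
    reduction == mean_before - mean_after holds exactly.
    """

    def _draw(values, given):
        if given is not None:
            return np.asarray(given, dtype=object)
        return np.asarray(values, dtype=object)[
            rng.integers(0, len(values), size=n)
        ]

    reduction = (
        rng.normal(10.0, 3.0, size=n)
        if reduction is None
        else np.asarray(reduction, dtype=float)
    )
    mean_before = np.abs(reduction) + rng.uniform(1.0, 5.0, size=n)
    df = pd.DataFrame(
        {
            "user_id": [f"u{i:05d}" for i in range(n)],
            "reduction": reduction,
            "mean_before": mean_before,
            "mean_after": mean_before - reduction,
            "gender": _draw(["female", "male"], gender),
            "age_bin": _draw(["under30", "over30"], age_bin),
            "race": _draw(["white", "black", "asian", "latinx"], race),
            "affiliation": _draw(
                ["democrat", "republican", "unknown"], affiliation
            ),
            "density_cat": _draw(["high", "low"], density_cat),
        }
    )
    df["density"] = np.where(df["density_cat"] == "high", 200.0, 20.0) + (
        rng.uniform(0, 5, size=n)
    )
    df["risk"] = rng.uniform(1000, 90000, size=n)
    df["trust_age"] = np.where(df["age_bin"] == "under30", 19.0, 20.3)
    df["trust_race"] = df["race"].map(
        {"white": 17.0, "black": 25.0, "asian": 28.0, "latinx": 26.0}
    )
    df["home_state"] = "A"
    return df


@pytest.fixture
def make_cohort_fn(rng):
    return lambda n, **kw: make_cohort(n, rng, **kw)


def utc(y, m, d, h=12):
    return dt.datetime(y, m, d, h, tzinfo=dt.timezone.utc)
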