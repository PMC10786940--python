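"""Readers and writers for posts, profiles and lookup tables.

Posts travel as JSON Lines (one object per line with keys ``user_id, ts,
lat, lon``) or CSV with the same headers.  Timestamps must be explicit UTC
(``...Z`` or ``...+00:00``); naive local times are rejected rather than
guessed, since week boundaries depend on the date.  Malformed lines are
counted and reported; the read aborts when their fraction exceeds the
configured tolerance.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import pandas as pd

from .geo import ValidationError

__all__ = [
    "read_posts",
    "write_posts",
    "read_profiles",
    "write_profiles",
    "read_state_table",
    "read_two_column_map",
    "read_hashtag_list",
]

_POST_KEYS = ("user_id", "ts", "lat", "lon")


def _is_utc_iso(ts: str) -> bool:
    return isinstance(ts, str) and (ts.endswith("Z") or ts.endswith("+00:00"))


def read_posts(path, tolerance: float = 0.0) -> pd.DataFrame:
    """Read a geotagged post stream.

    Returns a DataFrame ``user_id`` (category), ``ts`` (UTC datetime64),
    ``lat``, ``lon``.  Lines failing validation (missing keys, unparsable or
    non-UTC timestamps, coordinates out of range) are collected; if their
    fraction exceeds ``tolerance`` a :class:`ValidationError` naming the
    first offending line numbers is raised, otherwise they are dropped and
    counted in ``df.attrs["n_malformed"]``.
    """
    path = Path(path)
    if path.suffix in (".jsonl", ".json", ".ndjson"):
        rows, bad = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                    rows.append(
                        (obj["user_id"], obj["ts"], float(obj["lat"]), float(obj["lon"]))
                    )
                except (KeyError, ValueError, TypeError):
                    bad.append(lineno)
        df = pd.DataFrame(rows, columns=_POST_KEYS)
        offset = 0
    else:
        raw = pd.read_csv(path, dtype={"user_id": str, "ts": str})
        missing = [k for k in _POST_KEYS if k not in raw.columns]
        if missing:
            raise ValidationError(f"posts file lacks columns {missing}")
        df = raw[list(_POST_KEYS)].copy()
        bad = []
        offset = 1  # header line

    n_total = len(df) + len(bad)
    utc_ok = df["ts"].map(_is_utc_iso)
    ts = pd.to_datetime(df["ts"].where(utc_ok), errors="coerce", utc=True)
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    ok = (
        ts.notna()
        & lat.between(-90.0, 90.0)
        & (lon > -180.0)
        & (lon <= 180.0)
    )
    bad_rows = df.index[~ok]
    bad = sorted(bad + [int(i) + 1 + offset for i in bad_rows])
    if n_total == 0:
        raise ValidationError(f"{path}: no post records")
    if len(bad) / n_total > tolerance:
        raise ValidationError(
            f"{path}: {len(bad)}/{n_total} malformed post lines "
            f"(first: {bad[:10]})"
        )
    out = pd.DataFrame(
        {
            "user_id": df.loc[ok, "user_id"].astype("category"),
            "ts": ts[ok],
            "lat": lat[ok].astype(float),
            "lon": lon[ok].astype(float),
        }
    ).reset_index(drop=True)
    out.attrs["n_malformed"] = len(bad)
    return out


def write_posts(posts: pd.DataFrame, path) -> None:
    """Write posts as JSON Lines (or CSV when the suffix is .csv)."""
    path = Path(path)
    ts = posts["ts"].dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    if path.suffix == ".csv":
        out = posts.assign(ts=ts)[list(_POST_KEYS)]
        out.to_csv(path, index=False)
        return
    with open(path, "w") as fh:
        for uid, t, la, lo in zip(posts["user_id"], ts, posts["lat"], posts["lon"]):
            fh.write(
                json.dumps(
                    {"user_id": str(uid), "ts": t, "lat": float(la), "lon": float(lo)}
                )
                + "\n"
            )


def read_profiles(path) -> pd.DataFrame:
    """Read user attribute records (JSON Lines).

    Keys: ``user_id, gender, age_group, race, is_org, follows, hashtags``;
    missing label keys default to ``unknown`` / empty.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                rows.append(
                    {
                        "user_id": str(obj["user_id"]),
                        "gender": obj.get("gender", "unknown"),
                        "age_group": obj.get("age_group", "unknown"),
                        "race": obj.get("race", "unknown"),
                        "is_org": bool(obj.get("is_org", False)),
                        "follows": list(obj.get("follows", [])),
                        "hashtags": list(obj.get("hashtags", [])),
                    }
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValidationError(f"{path}:{lineno}: bad profile ({exc})")
    return pd.DataFrame(rows)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in profiles.iterrows():
            fh.write(
                json.dumps(
                    {
                        "user_id": str(r["user_id"]),
                        "gender": r["gender"],
                        "age_group": r["age_group"],
                        "race": r["race"],
                        "is_org": bool(r["is_org"]),
                        "follows": list(r["follows"]),
                        "hashtags": list(r["hashtags"]),
                    }
                )
                + "\n"
            )


def read_state_table(path) -> pd.DataFrame:
    """State lookup: geometry boxes, density, 2016 vote, cumulative cases."""
    df = pd.read_csv(path)
    needed = {
        "state",
        "lat_min",
        "lat_max",
        "lon_min",
        "lon_max",
        "density_per_km2",
        "vote2016",
        "cum_cases",
    }
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"state table lacks columns {sorted(missing)}")
    return df


def read_two_column_map(path, key: str, value: str) -> dict:
    """Generic two-column CSV lookup (e.g. ``age_bin,trust``)."""
    df = pd.read_csv(path)
    for col in (key, value):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return dict(zip(df[key].astype(str), pd.to_numeric(df[value])))


def read_hashtag_list(path) -> list[str]:
    """One hashtag per line; '#' prefixes and case are normalised away."""
    with open(path) as fh:
        return [
            line.strip().lstrip("#").lower()
            for line in fh
            if line.strip() and not line.startswith("//")
        ]
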