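"""End-to-end orchestration: index -> cohort -> ANOVA battery -> regressions.

:func:`run_analysis` composes the stages on in-memory tables and returns a
report bundle (dict of DataFrames plus a manifest with row counts at every
stage boundary); :func:`run_pipeline` wraps it with file I/O from a
:class:`PipelineConfig` and writes CSV/JSON outputs.  All outputs are plain
text for audit transparency, and every source of randomness flows from the
single configured seed.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .anova import (
    AnovaSpec,
    MobilityAnova,
    before_after_distributions,
    group_summary,
    tukey_hsd,
)
from .cohort import StudyWindow, build_cohort
from .geo import ValidationError, weekly_mobility_table
from .io import (
    read_hashtag_list,
    read_posts,
    read_profiles,
    read_state_table,
    read_two_column_map,
)
from .regression import (
    DEMOGRAPHIC_PREDICTORS,
    TRUST_PREDICTORS,
    ReductionRegression,
    RegressionSpec,
    SeparationError,
)
from .simulate import TRUST_BY_AGEBIN, TRUST_BY_RACE

__all__ = ["PipelineConfig", "run_analysis", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Study constants, method selectors and file locations."""

    window: StudyWindow = dataclasses.field(default_factory=StudyWindow)
    index_variant: str = "gyration"
    index_ddof: int = 0
    include_empty_weeks_as_zero: bool = False
    affiliation_method: str = "congress"
    alpha: float = 0.05
    anova_factors: Sequence[str] = (
        "gender",
        "age_bin",
        "race",
        "affiliation",
        "density_cat",
    )
    max_interaction_order: int = 3
    ss_type: str = "II"
    regression_designs: Sequence[str] = (
        "linear_positive",
        "loglinear_positive",
        "logistic_split",
    )
    regression_predictor_sets: Sequence[str] = ("demographic", "trust")
    seed: int = 0
    # input paths (all optional when tables are passed in-memory)
    posts_path: str | None = None
    profiles_path: str | None = None
    state_table_path: str | None = None
    covid_hashtags_path: str | None = None
    distancing_hashtags_path: str | None = None
    trust_by_race_path: str | None = None
    trust_by_agebin_path: str | None = None
    out_dir: str = "socmob_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        window = raw.pop("window", None)
        kwargs = {}
        if window:
            kwargs["window"] = StudyWindow(
                start=_dt.date.fromisoformat(str(window["start"])),
                cut=_dt.date.fromisoformat(str(window["cut"])),
                end=_dt.date.fromisoformat(str(window["end"])),
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def digest(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), default=str, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_PREDICTOR_SETS = {
    "demographic": DEMOGRAPHIC_PREDICTORS,
    "trust": TRUST_PREDICTORS,
}


def run_analysis(
    posts: pd.DataFrame,
    profiles: pd.DataFrame,
    state_table: pd.DataFrame,
    config: PipelineConfig,
    *,
    dem_accounts: Sequence[str],
    rep_accounts: Sequence[str],
    covid_hashtags: Sequence[str],
    distancing_hashtags: Sequence[str],
    trust_by_race: Mapping[str, float] | None = None,
    trust_by_agebin: Mapping[str, float] | None = None,
) -> dict:
    """Run every analysis stage on in-memory tables.

    Returns a bundle: ``weekly``, ``cohort``, ``exclusions``, ``anova``
    (term table), ``tukey`` (per multi-level factor), ``posthoc``,
    ``group_summary``, ``before_after``, ``regressions`` (per design and
    predictor set) and ``manifest``.
    """
    trust_by_race = dict(trust_by_race or TRUST_BY_RACE)
    trust_by_agebin = dict(trust_by_agebin or TRUST_BY_AGEBIN)

    weekly = weekly_mobility_table(
        posts, variant=config.index_variant, ddof=config.index_ddof
    )
    cohort, exclusions = build_cohort(
        profiles,
        weekly,
        posts,
        window=config.window,
        state_table=state_table,
        dem_accounts=dem_accounts,
        rep_accounts=rep_accounts,
        covid_hashtags=covid_hashtags,
        distancing_hashtags=distancing_hashtags,
        trust_by_race=trust_by_race,
        trust_by_agebin=trust_by_agebin,
        affiliation_method=config.affiliation_method,
        include_empty_weeks_as_zero=config.include_empty_weeks_as_zero,
    )

    model = MobilityAnova(
        cohort,
        AnovaSpec(
            factors=tuple(config.anova_factors),
            max_interaction_order=config.max_interaction_order,
            ss_type=config.ss_type,
        ),
    )
    res = model.fit()

    tukey = {}
    for factor in config.anova_factors:
        if model.data[factor].astype(str).nunique() >= 3:
            tukey[factor] = tukey_hsd(model.data, factor, alpha=config.alpha)
    posthoc = res.posthoc_pairwise(alpha=config.alpha)

    summaries = []
    dists = []
    for factor in config.anova_factors:
        s = group_summary(model.data, factor)
        s.insert(0, "factor", factor)
        summaries.append(s)
        d = before_after_distributions(cohort, factor)
        d.insert(0, "factor", factor)
        dists.append(d)
    summary_tbl = pd.concat(summaries, ignore_index=True)
    dist_tbl = pd.concat(dists, ignore_index=True)

    regressions = {}
    for design in config.regression_designs:
        for pset in config.regression_predictor_sets:
            key = f"{design}/{pset}"
            spec = RegressionSpec(
                design=design, predictors=_PREDICTOR_SETS[pset]
            )
            try:
                fit = ReductionRegression(cohort, spec).fit()
                regressions[key] = {
                    "params": fit.params,
                    "meta": fit.meta,
                }
            except (ValidationError, SeparationError) as exc:
                regressions[key] = {"error": str(exc)}

    manifest = {
        "socmob_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": _versions(),
        "counts": {
            "posts": int(len(posts)),
            "user_weeks": int(len(weekly)),
            "users_input": int(len(profiles)),
            "cohort": int(len(cohort)),
            "excluded": int(len(exclusions)),
            "anova_n": int(res.nobs),
            **{
                f"regression_n/{k}": int(v["meta"]["n_used"])
                for k, v in regressions.items()
                if "meta" in v
            },
        },
    }
    _check_manifest(manifest)
    return {
        "weekly": weekly,
        "cohort": cohort,
        "exclusions": exclusions,
        "anova": res,
        "tukey": tukey,
        "posthoc": posthoc,
        "group_summary": summary_tbl,
        "before_after": dist_tbl,
        "regressions": regressions,
        "manifest": manifest,
    }


def _check_manifest(manifest: dict) -> None:
    c = manifest["counts"]
    if not (
        c["posts"] >= c["user_weeks"]
        and c["users_input"] == c["cohort"] + c["excluded"]
        and c["anova_n"] <= c["cohort"]
    ):
        raise ValidationError(f"inconsistent stage counts: {c}")


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based end-to-end run; writes all outputs under ``out_dir``."""
    for field in ("posts_path", "profiles_path", "state_table_path"):
        if getattr(config, field) is None:
            raise ValidationError(f"config missing {field}")
    posts = read_posts(config.posts_path)
    profiles = read_profiles(config.profiles_path)
    state_table = read_state_table(config.state_table_path)

    from .simulate import (
        COVID_HASHTAGS,
        DEM_CONGRESS,
        DISTANCING_HASHTAGS,
        REP_CONGRESS,
    )

    covid = (
        read_hashtag_list(config.covid_hashtags_path)
        if config.covid_hashtags_path
        else list(COVID_HASHTAGS)
    )
    dist = (
        read_hashtag_list(config.distancing_hashtags_path)
        if config.distancing_hashtags_path
        else list(DISTANCING_HASHTAGS)
    )
    trust_race = (
        read_two_column_map(config.trust_by_race_path, "race", "trust")
        if config.trust_by_race_path
        else None
    )
    trust_age = (
        read_two_column_map(config.trust_by_agebin_path, "age_bin", "trust")
        if config.trust_by_agebin_path
        else None
    )
    bundle = run_analysis(
        posts,
        profiles,
        state_table,
        config,
        dem_accounts=DEM_CONGRESS,
        rep_accounts=REP_CONGRESS,
        covid_hashtags=covid,
        distancing_hashtags=dist,
        trust_by_race=trust_race,
        trust_by_agebin=trust_age,
    )
    write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: dict, out_dir) -> None:
    """Write the report bundle as CSV tables plus one JSON report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["weekly"].to_csv(out / "user_week_mobility.csv", index=False)
    bundle["cohort"].to_csv(out / "cohort.csv", index=False)
    bundle["exclusions"].to_csv(out / "exclusions.csv", index=False)
    bundle["anova"].table.to_csv(out / "anova_terms.csv", index=False)
    for factor, tbl in bundle["tukey"].items():
        tbl.to_csv(out / f"tukey_{factor}.csv", index=False)
    bundle["posthoc"].to_csv(out / "posthoc.csv", index=False)
    bundle["group_summary"].to_csv(out / "group_summary.csv", index=False)
    bundle["before_after"].to_csv(out / "before_after.csv", index=False)
    for key, reg in bundle["regressions"].items():
        stem = key.replace("/", "_")
        if "params" in reg:
            reg["params"].to_csv(out / f"regression_{stem}.csv", index=False)
    report = {
        "manifest": bundle["manifest"],
        "anova": bundle["anova"].table.to_dict(orient="records"),
        "regressions": {
            k: (
                {
                    "meta": _jsonable(v["meta"]),
                    "params": v["params"].to_dict(orient="records"),
                }
                if "params" in v
                else v
            )
            for k, v in bundle["regressions"].items()
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=1, default=str)


def _jsonable(meta: dict) -> dict:
    return json.loads(json.dumps(meta, default=str))


def _versions() -> dict:
    import numpy
    import scipy
    import statsmodels

    return {
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
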