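# socmob

Social-mobility analysis of geotagged post streams.

`socmob` is for computational epidemiologists and computational social
scientists who study behaviour change — social distancing in particular —
through the location traces people leave in geotagged social-media posts.
It turns a raw stream of check-ins into a per-user weekly mobility measure,
builds a labeled one-row-per-user cohort around a policy cut date, and runs
the standard inferential battery on the resulting *mobility reduction*:
factorial ANOVA with post-hoc tests, and regressions on trust-in-government
and perceived risk.

## The statistic

For user *u* and ISO week *w* with geotagged points *p₁ … pₙ*, the
**social-mobility index** is the radius of gyration about the week's
spherical centroid *c*:

```
SMI(u, w) = sqrt( (1/n) Σᵢ d(pᵢ, c)² )        [km]
```

where *d* is the great-circle (haversine) distance on a sphere of radius
R = 6371.0088 km and *c* is the normalised 3-D mean of the unit position
vectors. A week spent at one location scores 0; a week ranging over a city
scores roughly the city's extent. Repeated identical coordinates each
count, and `1/(n−1)` scaling or a consecutive-distance variant are
available as sensitivity options.

The **mobility reduction** of a user is the mean weekly SMI over the
*before* period minus the mean over the *after* period, split at the
social-distancing cut date (defaults: 2019-01-01 … 2020-03-15 vs
2020-03-16 … 2020-06-21). Positive reduction = less movement after the
cut. Reduction is then analysed against gender, age bin (under/over 30),
race/ethnicity, political affiliation (follow-based or state-vote
labeling), state population-density category, hashtag usage flags, and
group-level trust / state-level risk covariates.

## Worked example

Everything is testable without any external data via the bundled synthetic
generator, which plants known group-level reduction effects:

```python
from socmob import SyntheticConfig, simulate_dataset
from socmob.pipeline import PipelineConfig, run_analysis
from socmob.simulate import (DEM_CONGRESS, REP_CONGRESS,
                             COVID_HASHTAGS, DISTANCING_HASHTAGS)

cfg = SyntheticConfig(n_users=5000, seed=42)
profiles, posts, gt = simulate_dataset(cfg)       # 2,737,571 posts
bundle = run_analysis(
    posts, profiles, cfg.state_table,
    PipelineConfig(seed=42, max_interaction_order=2),
    dem_accounts=DEM_CONGRESS, rep_accounts=REP_CONGRESS,
    covid_hashtags=COVID_HASHTAGS, distancing_hashtags=DISTANCING_HASHTAGS)
print(bundle["anova"].summary())
```

```
Mobility reduction ANOVA (type II SS, n=4333, residual df=4300)

                   term     F  df        p
                 gender  9.63   1  0.00192
                age_bin 28.31   1 1.08e-07
                   race 15.89   3 2.85e-10
            affiliation 11.58   2 9.67e-06
            density_cat 13.83   1 0.000203
         gender:age_bin  1.25   1    0.264
            ...
affiliation:density_cat  4.14   2    0.016
```

All five planted main effects are flagged (the generator gives, e.g.,
Democrats a larger fractional reduction than Republicans), while the
non-planted interactions stay quiet. The group summary mirrors the
planted ordering in km of reduction:

```
     factor      level  mean_reduction    n
affiliation   democrat       14.553400  618
affiliation republican       12.045050  273
affiliation    unknown       11.187496 3442
```

and the trust-substituted linear regression on users with positive
reduction recovers positive trust coefficients:

```
     term      coef  std_error            p
    const 13.174476   1.051781 2.536331e-35
trust_age  2.086016   0.536077 1.013798e-04
trust_race 1.449290   0.666940 2.983666e-02
...
```

`bundle` also carries the weekly index table, the cohort and exclusion
log, Tukey HSD tables for multi-level factors, Bonferroni-corrected
pairwise cell comparisons for significant interactions, before/after
distribution summaries, and a manifest with row counts at every stage.

## Command line

```
socmob simulate --seed 3 --n-users 2000 --out data/     # synthetic dataset
socmob index    --posts data/posts.jsonl --out weekly.csv
socmob run      --config config.yaml --seed 3           # all stages
```

`run`/`cohort`/`anova`/`regress` take a YAML config naming the input
files (`posts_path`, `profiles_path`, `state_table_path`, optional hashtag
and trust tables), the study window, method selectors and the output
directory. Exit codes: 0 ok, 1 validation error, 2 runtime failure.

Posts are JSON Lines or CSV with `user_id, ts, lat, lon` (timestamps must
be explicit UTC). The cohort CSV has one row per user with columns, in
order: `user_id, mean_before, mean_after, reduction, gender, age_group,
age_bin, race, affiliation, follows_trump, home_state, home_lat, home_lon,
density, density_cat, covid_hashtag, distancing_hashtag, trust_race,
trust_age, risk, n_weeks_before, n_weeks_after, n_posts,
weekly_post_rate`; the exclusion log is `user_id, reason`.

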