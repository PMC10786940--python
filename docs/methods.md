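# Methods

This note documents the models and procedures implemented in `socmob`, the
defaults and their units, the synthetic generator's assumptions, and the
numerical choices made where the design was genuinely open.

## Weekly social-mobility index

The index of a user-week is the population-form radius of gyration of the
week's geotagged points about their spherical centroid: the root of the
mean squared great-circle distance to the centroid, in km. Choices:

- **Distance metric.** Haversine on a sphere with the IUGG mean radius
  R = 6371.0088 km. At the sub-500-km scale of human check-ins, the
  spherical error relative to an ellipsoidal geodesic is far below the
  noise of the measure itself.
- **Centroid.** Normalised 3-D mean of unit position vectors —
  deterministic, permutation-invariant, and exact on the sphere. A mean
  vector with norm below 1e-9 (an essentially antipodal point set) is
  refused as degenerate rather than silently resolved.
- **1/n, not 1/(n−1).** The gyration radius is a population dispersion of
  the week's observed locations, not an estimate of a hypothetical
  larger sample; a single-post week is a genuine zero (the user was seen
  at one place). The sample form (`ddof=1`) and a consecutive-distance
  variant (standard deviation of distances between successive check-ins)
  are exposed for sensitivity analyses.
- **Weeks.** ISO-8601, Monday-start, keyed by (ISO year, ISO week); week
  membership in the before/after periods follows the week's Monday. All
  timestamps are required to be explicit UTC; naive local times are
  rejected rather than guessed because week boundaries depend on the date.
- **Exact zeros.** A week whose posts all carry one coordinate scores
  exactly 0.0, short-circuiting the floating-point path.
- **Empty weeks.** Weeks without posts are absent from a user's series:
  no geotagged activity is not evidence of zero movement. Counting them
  as zero-mobility weeks is available as a config switch
  (`include_empty_weeks_as_zero`); it can only lower period means, never
  raise them.

## Cohort construction

The study window defaults to 2019-01-01 … 2020-06-21 with the cut at
2020-03-16, the date of the US national "Slow the Spread" announcement.
Users enter the cohort when they have at least one geotagged week in each
period and are not flagged as organizational accounts (the flag is
consumed from the input, never inferred). Every excluded user is logged
with a reason code (`organization`, `absent_before`, `absent_after`,
`no_posts`), so cohort + exclusions exactly conserve the input users.

Period means weight observed weeks equally regardless of post count (a
post-weighted alternative would conflate posting intensity with
mobility); reduction = mean_before − mean_after, in km.

Labeling rules:

- **Home location** is the spherical centroid of all of the user's posts
  in the window; the home state comes from a pluggable point-to-state
  function. The default ships axis-aligned bounding boxes (exact,
  dependency-free); real deployments supply their own geometry.
- **Density category**: `high` iff the home state's population density
  strictly exceeds the median over the density table; states at the
  median are `low` (a deterministic, documented tie-break).
- **Political affiliation** from follow lists: a user following accounts
  of exactly one party's members of Congress (or congressional
  leadership, per the method selector) gets that party's label; following
  neither — or both — yields `unknown`, the conservative symmetric
  choice. A state-vote method (2016 presidential result of the home
  state) is also available. The Trump handle is removed from both party
  lists before labeling and tracked as a separate boolean, since that
  account's popularity would otherwise swamp the follow signal.
- **Age** collapses to under/over 30. **Unknown** gender/age/race are
  retained in the cohort but dropped listwise from any analysis using
  that variable; political `unknown` is a modeled level throughout,
  because unlabeled users are the large majority and scientifically
  interesting in their own right.
- **Trust and risk.** Group-level trust-in-government scores attach by
  age bin (19.0 under 30, 20.3 over 30, population-weighted collapses of
  generation-level survey values) and by race/ethnicity (table supplied
  by the user; the bundled per-race values are synthetic stand-ins).
  Perceived risk is the home state's cumulative confirmed case count at
  the window end, used raw (no per-capita adjustment) and min-max scaled
  inside regressions.

## ANOVA battery

The response is always the per-user reduction (km). The main model is a
factorial ANOVA over gender, age bin, race/ethnicity, political
affiliation and density category with interactions up to order 3 (the
depth at which three-way demographic interactions become interpretable;
configurable). Choices:

- **Type II sums of squares** by default: the cohort is unbalanced, and
  Type II is invariant to factor order without requiring the
  contrast-coding care of Type III. Type III is available via
  `ss_type="III"` and reported as such.
- Designs with empty interaction cells are refused with an explicit
  singularity error instead of silently dropping aliased terms; zero
  residual variance (a degenerate response) is likewise an error.
- **Tukey HSD** covers all pairwise level comparisons of a single factor
  with three or more levels (race/ethnicity, affiliation).
- **Interaction post-hocs** are Welch two-sample t-tests (robust to the
  unequal cell variances an unbalanced cohort guarantees) between every
  pair of cells of each significant interaction, Bonferroni-corrected
  within that interaction's family: p_corrected = min(1, m·p_raw) with m
  the number of tests actually performed. Cells with fewer than two
  observations are skipped and reported, not silently dropped.
- α = 0.05 declares terms significant before post-hoc analysis.

## Regression designs

Per-user reduction is strongly non-normal (a spike near zero, long tails
both sides), so the analysis splits by sign: users with zero mobility in
both periods are removed; the rest partition into reduction > 0 and
reduction ≤ 0. Three designs:

1. `linear_positive` — OLS of reduction on the predictors, positive group;
2. `loglinear_positive` — the same rows with response log(reduction + 1);
3. `logistic_split` — logistic regression of 1[reduction > 0] on the
   whole split cohort.

Two predictor sets ship as defaults: *demographic* (risk, gender, age
bin, race, affiliation, exact density values) and *trust* (age and race
replaced by the trust measures; gender and affiliation retained, risk and
density kept as controls — "replace age and race" is read narrowly).
Encoding rules: categorical predictors are dummy-coded against the
largest observed level, except affiliation whose reference is always
Democrat (its largest level is `unknown`, a meaningless baseline);
numeric predictors are min-max scaled to [0, 1] over the rows entering
each fit, with the bounds recorded in the result metadata. The min-max
rule is applied to the numeric *independent* variables only — scaling the
response of a logistic model would be meaningless — and the response is
never normalized. Rank-deficient designs fail with the offending columns
named; logistic fits that fail to converge or blow past |β| > 50 are
flagged as (quasi-)separation rather than reported.

## Synthetic generator

The generator exists so every stage is testable end to end with known
ground truth. Per user: attributes drawn independently from configured
marginals; a home state drawn from state weights and a home point uniform
in the state's box; a persistent dispersion scale σ_before, lognormal
across users; and a planted fractional reduction
f = clip(base + Σ effects of the user's levels, 0, 0.95). Per user-week:
active with probability `p_active_week`; if active, 1 + Poisson(rate − 1)
posts, each at home + a displacement with half-normal radial distance
|N(0, σ_w)| and uniform bearing in the local tangent plane, with

    σ_w = σ_before · (1 − f·1[week ≥ cut]) · exp(N(0, noise_sd)).

Because the index is scale-equivariant in σ, the expected after/before
index ratio is exactly 1 − f, which makes group-level expectations exact
oracles. Follow sets and hashtags are generated consistently with the
drawn affiliation and flags, so the labeling rules round-trip.

Defaults and why:

- `weekly_post_rate = 14.25` posts per active week — the reported average
  weekly geotagged-post rate for this kind of collection.
- `p_active_week = 0.5` — geotagged posting is intermittent; users are
  present in roughly half of calendar weeks. This also leaves the
  before/after-presence filter with a small, realistic exclusion rate.
- `sigma_log_median_km = 25`, `sigma_log_sd = 0.8` — weekly travel scales
  of a few to ~100 km with a heavy right tail, the regime of real
  radius-of-gyration distributions.
- `noise_sd = 0.6` (log scale): weekly dispersion varies by a factor of
  ~1.8 around its mean week to week. This matters qualitatively: with
  much smaller jitter essentially every simulated user realises a
  positive reduction, the sign split degenerates to a single class, and
  the logistic design is unfittable — unlike real data, where many users
  show no reduction. 0.6 produces a populated non-positive group (~10%)
  while leaving planted effects recoverable.
- `base_effect = 0.15` with additive steps of 0.05 per ordered level
  (male > female, over-30 > under-30, Asian > Latinx > White > Black,
  Democrat > Republican > unknown, high > low density): every group
  reduces mobility, with group orderings mirroring the qualitative
  pattern the analysis is designed to detect. Attribute marginals follow
  the published summary-table shares (≈57% male, 54% under 30, 80%
  politically unlabeled, ~10% organizational accounts).
- Ten toy states on a 5×2 grid of 6°×5° boxes with densities straddling
  their median; denser states get more users, more cases and Democratic
  2016 votes.

What the generator does **not** emulate: realistic trajectory structure
(Lévy flights, exploration/preferential-return), within-state geography
(homes are uniform in a box; density is a state-level constant),
attribute correlations (gender, age, race, affiliation and state are
drawn independently, unlike any real population), text content, social
network structure, or seasonal/weekday posting rhythms. Passing the
recovery tests therefore shows the *pipeline* is correct and calibrated —
it does not validate the substantive findings on real data, where
confounding between these attributes is the central difficulty.

## Verification problem sizes

The package's verification battery (tests and `scripts/acceptance.py`)
uses: 1,000 random point sets against an independently coded brute-force
gyration radius (tolerance 1e-6 relative); 1,000 null one-way replicates
of 2,000 users for type-I calibration (rejection rate 0.05 ± 0.02, and
F = t² to 1e-8 on balanced designs); 20 seeded end-to-end replicates of
20,000 users for planted-effect recovery (all five main effects at
p < 0.01 and ground-truth group orderings in ≥95% of replicates); and
100/100/60 replicates at n = 5,000–10,000 for the three regression
designs (planted coefficient within 2 SE in ≥90%). These sizes give each
check comfortable statistical margin while keeping the battery a
desk-scale computation.

## Known limitations

- Geodesy is spherical; no ellipsoidal correction.
- The bounding-box state geometry is for testing; real analyses must
  supply true state polygons, and the centroid-based home location can
  fall outside every state (flagged `unknown`).
- Trust scores are group-level constants, so their regression
  coefficients inherit the ecological caveat: they compare groups, not
  individuals.
- The pipeline consumes demographic labels; it neither infers them nor
  models their misclassification error.
- Bonferroni within interaction families is conservative when families
  overlap; no across-family correction is attempted.
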