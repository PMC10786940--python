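"""Factorial ANOVA of mobility reduction, with Tukey and Bonferroni post-hocs.

The central question is whether demographic groups differ in how much they
reduced their weekly mobility after the social-distancing cut date.  The
model is a factorial ANOVA of the per-user reduction (km) on categorical
factors (age bin, gender, race/ethnicity, political affiliation, state
density category by default) with interactions up to a configurable order,
followed by

* Tukey HSD over the levels of a single multi-level factor,
* Welch pairwise t-tests between the cells of each significant interaction,
  Bonferroni-corrected within that interaction's family.

Organised as a Model/Results pair: :class:`MobilityAnova` holds data and
design, ``fit()`` returns :class:`MobilityAnovaResults` carrying the term
table and the post-hoc machinery.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .geo import ValidationError

__all__ = [
    "AnovaSpec",
    "MobilityAnova",
    "MobilityAnovaResults",
    "tukey_hsd",
    "posthoc_pairwise",
    "group_summary",
    "before_after_distributions",
]

DEFAULT_FACTORS = ("gender", "age_bin", "race", "affiliation", "density_cat")

#: factors whose "unknown" level is a modeled group rather than missingness
UNKNOWN_IS_LEVEL = ("affiliation",)


@dataclasses.dataclass
class AnovaSpec:
    """Design of one ANOVA run.

    ``ss_type`` selects Type II (default, order-invariant for unbalanced
    designs without strong interaction aliasing) or Type III sums of
    squares.  Interactions of every subset of the factors up to
    ``max_interaction_order`` are included.
    """

    response: str = "reduction"
    factors: Sequence[str] = DEFAULT_FACTORS
    max_interaction_order: int = 3
    ss_type: str = "II"

    def __post_init__(self):
        if not self.factors:
            raise ValidationError("AnovaSpec needs at least one factor")
        if self.ss_type not in ("II", "III"):
            raise ValidationError(f"ss_type must be II or III, got {self.ss_type!r}")
        if self.max_interaction_order < 1:
            raise ValidationError("max_interaction_order must be >= 1")

    def formula(self) -> str:
        terms = []
        order = min(self.max_interaction_order, len(self.factors))
        for k in range(1, order + 1):
            for combo in itertools.combinations(self.factors, k):
                terms.append(":".join(f"C({f})" for f in combo))
        return f"{self.response} ~ " + " + ".join(terms)


def listwise_known(
    cohort: pd.DataFrame, factors: Sequence[str], response: str | None = None
) -> pd.DataFrame:
    """Drop rows with an "unknown" label in any factor where unknown means
    missing (political affiliation keeps its unknown level), and rows with a
    missing response."""
    mask = pd.Series(True, index=cohort.index)
    for f in factors:
        if f not in UNKNOWN_IS_LEVEL:
            mask &= cohort[f].astype(str) != "unknown"
        mask &= cohort[f].notna()
    if response is not None:
        mask &= cohort[response].notna()
    return cohort.loc[mask]


class MobilityAnova:
    """Factorial ANOVA model of mobility reduction on categorical factors."""

    def __init__(self, cohort: pd.DataFrame, spec: AnovaSpec | None = None):
        self.spec = spec or AnovaSpec()
        missing = [
            c
            for c in (self.spec.response, *self.spec.factors)
            if c not in cohort.columns
        ]
        if missing:
            raise ValidationError(f"cohort lacks columns {missing}")
        self.data = listwise_known(
            cohort, self.spec.factors, self.spec.response
        ).copy()
        for f in self.spec.factors:
            levels = self.data[f].astype(str).nunique()
            if levels < 2:
                raise ValidationError(
                    f"factor {f!r} has {levels} observed level(s); need >= 2"
                )

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        factors: Sequence[str] = DEFAULT_FACTORS,
        response: str = "reduction",
        max_interaction_order: int = 3,
        ss_type: str = "II",
    ) -> "MobilityAnova":
        return cls(
            cohort,
            AnovaSpec(
                response=response,
                factors=tuple(factors),
                max_interaction_order=max_interaction_order,
                ss_type=ss_type,
            ),
        )

    def fit(self) -> "MobilityAnovaResults":
        formula = self.spec.formula()
        ols_fit = smf.ols(formula, data=self.data).fit()
        if ols_fit.df_resid <= 0:
            raise ValidationError("saturated design: no residual df")
        # aliased (empty-cell) designs: statsmodels drops nothing, rank check
        rank = np.linalg.matrix_rank(ols_fit.model.exog)
        if rank < ols_fit.model.exog.shape[1]:
            raise ValidationError(
                "singular design (empty cells alias some interaction terms); "
                "reduce max_interaction_order or merge levels"
            )
        tss = float(ols_fit.centered_tss)
        if tss > 0 and ols_fit.ssr <= 1e-12 * tss:
            raise ValidationError(
                "zero residual variance: F statistics undefined"
            )
        typ = 2 if self.spec.ss_type == "II" else 3
        table = sm.stats.anova_lm(ols_fit, typ=typ)
        table = table.rename(
            columns={"PR(>F)": "p", "F": "F", "df": "df", "sum_sq": "sum_sq"}
        )
        table.index = [
            idx.replace("C(", "").replace(")", "") for idx in table.index
        ]
        return MobilityAnovaResults(self, ols_fit, table)


class MobilityAnovaResults:
    """Term table plus post-hoc analyses for a fitted :class:`MobilityAnova`."""

    def __init__(self, model: MobilityAnova, ols_fit, table: pd.DataFrame):
        self.model = model
        self._ols = ols_fit
        raw = table
        resid = raw.loc[raw.index.str.contains("Residual")]
        self.residual_df = int(resid["df"].iloc[0])
        terms = raw.loc[~raw.index.str.contains("Residual")].copy()
        if "Intercept" in terms.index:
            terms = terms.drop(index="Intercept")
        self.table = pd.DataFrame(
            {
                "term": terms.index,
                "F": terms["F"].to_numpy(),
                "df": terms["df"].to_numpy().astype(int),
                "p": terms["p"].to_numpy(),
            }
        ).reset_index(drop=True)

    @property
    def nobs(self) -> int:
        return int(self._ols.nobs)

    def significant_terms(self, alpha: float = 0.05) -> list[str]:
        sig = self.table.loc[self.table["p"] < alpha, "term"]
        return list(sig)

    def term_p(self, term: str) -> float:
        row = self.table.loc[self.table["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["p"].iloc[0])

    # ---- post-hocs ------------------------------------------------------
    def tukey(self, factor: str, alpha: float = 0.05) -> pd.DataFrame:
        return tukey_hsd(self.model.data, factor,
                         response=self.model.spec.response, alpha=alpha)

    def posthoc_pairwise(
        self, alpha: float = 0.05, interactions: Sequence[str] | None = None
    ) -> pd.DataFrame:
        if interactions is None:
            interactions = [
                t for t in self.significant_terms(alpha) if ":" in t
            ]
        return posthoc_pairwise(
            self.model.data,
            list(interactions),
            alpha=alpha,
            response=self.model.spec.response,
        )

    def group_summary(self, factor: str, level_order=None) -> pd.DataFrame:
        return group_summary(
            self.model.data,
            factor,
            response=self.model.spec.response,
            level_order=level_order,
        )

    def summary(self) -> str:
        lines = [
            "Mobility reduction ANOVA "
            f"(type {self.model.spec.ss_type} SS, n={self.nobs}, "
            f"residual df={self.residual_df})",
            "",
            self.table.to_string(
                index=False,
                formatters={
                    "F": "{:.2f}".format,
                    "p": "{:.3g}".format,
                },
            ),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# standalone post-hoc operations (usable without fitting the full model)


def tukey_hsd(
    cohort: pd.DataFrame,
    factor: str,
    response: str = "reduction",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise level comparisons with Tukey HSD adjusted p-values.

    Intended for factors with three or more levels (race/ethnicity,
    political affiliation); two levels are already covered by the main
    effect and raise an error below that.
    """
    data = listwise_known(cohort, [factor], response)
    levels = data[factor].astype(str).unique()
    if len(levels) < 3:
        raise ValidationError(
            f"tukey_hsd needs >= 3 levels, factor {factor!r} has {len(levels)}"
        )
    res = pairwise_tukeyhsd(
        data[response].to_numpy(dtype=float),
        data[factor].astype(str).to_numpy(),
        alpha=alpha,
    )
    tbl = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    return pd.DataFrame(
        {
            "cell_a": tbl["group1"],
            "cell_b": tbl["group2"],
            "mean_diff": tbl["meandiff"].astype(float),
            "p_raw": tbl["p-adj"].astype(float),
            "p_corrected": tbl["p-adj"].astype(float),
            "significant": tbl["reject"].astype(bool),
        }
    )


def posthoc_pairwise(
    cohort: pd.DataFrame,
    interaction_terms: Sequence[str],
    alpha: float = 0.05,
    response: str = "reduction",
) -> pd.DataFrame:
    """Welch t-tests between every pair of cells of each interaction.

    A cell is one combination of the interaction's factor levels, e.g.
    ``male/over30``.  The Bonferroni family is all pairwise comparisons
    within one interaction term: ``p_corrected = min(1, m * p_raw)`` with
    ``m`` the number of tests actually performed in that family.  Cells with
    fewer than 2 observations are skipped and reported with NaN p-values.
    """
    rows = []
    for term in interaction_terms:
        factors = [f.strip() for f in term.split(":")]
        data = listwise_known(cohort, factors, response)
        cells = {
            "/".join(map(str, key if isinstance(key, tuple) else (key,))): grp[
                response
            ].to_numpy(dtype=float)
            for key, grp in data.groupby(factors, observed=True)
        }
        names = sorted(cells)
        fam = []
        for a, b in itertools.combinations(names, 2):
            xa, xb = cells[a], cells[b]
            if len(xa) < 2 or len(xb) < 2:
                fam.append((term, a, b, np.nan, np.nan, True))
                continue
            t = st.ttest_ind(xa, xb, equal_var=False)
            fam.append(
                (term, a, b, float(xa.mean() - xb.mean()), float(t.pvalue), False)
            )
        m = sum(1 for r in fam if not r[5])
        for term_, a, b, diff, p_raw, skipped in fam:
            p_corr = min(1.0, m * p_raw) if not skipped else np.nan
            rows.append(
                {
                    "interaction": term_,
                    "cell_a": a,
                    "cell_b": b,
                    "mean_diff": diff,
                    "p_raw": p_raw,
                    "p_corrected": p_corr,
                    "significant": (not skipped) and p_corr < alpha,
                    "skipped": skipped,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "interaction",
            "cell_a",
            "cell_b",
            "mean_diff",
            "p_raw",
            "p_corrected",
            "significant",
            "skipped",
        ],
    )


def group_summary(
    cohort: pd.DataFrame,
    factor: str,
    response: str = "reduction",
    level_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-level mean reduction and sample size (Table-1-style summary)."""
    if factor not in cohort.columns:
        raise ValidationError(f"no such factor {factor!r}")
    data = cohort.loc[cohort[response].notna()]
    g = data.groupby(data[factor].astype(str), observed=True)[response].agg(
        ["mean", "size"]
    )
    out = pd.DataFrame(
        {
            "level": g.index,
            "mean_reduction": g["mean"].to_numpy(),
            "n": g["size"].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    if level_order is not None:
        order = [l for l in level_order if l in set(out["level"])]
        out = (
            out.set_index("level").loc[order].reset_index()
        )
    return out


def before_after_distributions(
    cohort: pd.DataFrame,
    factor: str,
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> pd.DataFrame:
    """Per-level summaries of the before/after mean mobility distributions.

    Returns one row per (level, period) with mean, the requested quantiles
    and n — enough to regenerate before/after distribution plots.  Levels
    with no remaining observations are omitted.
    """
    if factor not in cohort.columns:
        raise ValidationError(f"no such factor {factor!r}")
    rows = []
    for period, col in (("before", "mean_before"), ("after", "mean_after")):
        data = cohort.loc[cohort[col].notna()]
        for level, grp in data.groupby(data[factor].astype(str), observed=True):
            vals = grp[col].to_numpy(dtype=float)
            row = {
                "level": level,
                "period": period,
                "mean": float(vals.mean()),
                "n": int(vals.size),
            }
            for q in quantiles:
                row[f"q{int(round(q * 100)):02d}"] = float(np.quantile(vals, q))
            rows.append(row)
    return pd.DataFrame(rows)
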