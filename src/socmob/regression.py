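"""Regression designs linking mobility reduction to trust, risk and density.

Because per-user mobility reduction is strongly non-normal (a point mass
near zero with long tails on both sides), the analysis splits users by the
sign of their reduction and runs three designs:

* ``linear_positive`` — OLS of reduction on the predictors, users with
  reduction > 0 only;
* ``loglinear_positive`` — the same rows, response log(reduction + 1);
* ``logistic_split`` — logistic regression of 1[reduction > 0] on the whole
  split cohort (positive vs non-positive), after removing users with zero
  mobility in both periods.

Categorical predictors are dummy-encoded against the largest observed level,
except political affiliation whose reference is always ``democrat`` (its
largest level is ``unknown``).  Numeric predictors are min-max scaled to
[0, 1] over the rows entering the fit; the response is never scaled.

Model/Results pair: :class:`ReductionRegression` -> ``fit()`` ->
:class:`ReductionRegressionResults`.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geo import ValidationError

__all__ = [
    "RegressionSpec",
    "SplitCohort",
    "split_by_reduction",
    "encode_design",
    "ReductionRegression",
    "ReductionRegressionResults",
    "DEMOGRAPHIC_PREDICTORS",
    "TRUST_PREDICTORS",
    "SeparationError",
]

#: design 1: perceived risk + categorical demographics (+ density control)
DEMOGRAPHIC_PREDICTORS: tuple = (
    ("risk", "numeric"),
    ("gender", "categorical"),
    ("age_bin", "categorical"),
    ("race", "categorical"),
    ("affiliation", "categorical"),
    ("density", "numeric"),
)

#: design 2: age and race replaced by the trust-in-government measures
TRUST_PREDICTORS: tuple = (
    ("risk", "numeric"),
    ("gender", "categorical"),
    ("affiliation", "categorical"),
    ("trust_age", "numeric"),
    ("trust_race", "numeric"),
    ("density", "numeric"),
)

#: reference level forced regardless of group size
FORCED_REFERENCES = {"affiliation": "democrat"}


class SeparationError(ValidationError):
    """Complete or quasi-complete separation in a logistic fit."""


@dataclasses.dataclass
class RegressionSpec:
    design: str = "linear_positive"
    predictors: Sequence[tuple] = DEMOGRAPHIC_PREDICTORS
    reference_levels: Mapping[str, str] = dataclasses.field(
        default_factory=dict
    )
    normalize_numeric: bool = True
    response: str = "reduction"

    def __post_init__(self):
        if self.design not in (
            "linear_positive",
            "loglinear_positive",
            "logistic_split",
        ):
            raise ValidationError(f"unknown design {self.design!r}")


@dataclasses.dataclass
class SplitCohort:
    """The sign-of-reduction partition; parts are disjoint and exhaustive."""

    positive: pd.DataFrame
    nonpositive: pd.DataFrame
    removed: pd.DataFrame

    def __iter__(self):
        return iter((self.positive, self.nonpositive, self.removed))


def split_by_reduction(cohort: pd.DataFrame) -> SplitCohort:
    """Partition users by the sign of their mobility reduction.

    Users with zero mobility in *both* periods are removed outright; the
    rest split into reduction > 0 and reduction <= 0 (a zero reduction with
    nonzero mobility is kept, in the non-positive group).
    """
    zero_both = (cohort["mean_before"] == 0) & (cohort["mean_after"] == 0)
    removed = cohort.loc[zero_both]
    rest = cohort.loc[~zero_both]
    positive = rest.loc[rest["reduction"] > 0]
    nonpositive = rest.loc[rest["reduction"] <= 0]
    assert len(positive) + len(nonpositive) + len(removed) == len(cohort)
    return SplitCohort(positive, nonpositive, removed)


def encode_design(
    cohort: pd.DataFrame, spec: RegressionSpec
) -> tuple[pd.DataFrame, dict]:
    """Dummy-encode categoricals and min-max scale numerics.

    Returns ``(X, meta)``: X has an intercept column ``const``, one dummy
    per non-reference level of each categorical (named ``factor[level]``)
    and one column per numeric predictor; meta records reference levels,
    scaling bounds and how many rows were dropped for unknown labels or
    missing numerics.
    """
    cats = [n for n, k in spec.predictors if k == "categorical"]
    nums = [n for n, k in spec.predictors if k == "numeric"]
    for name in cats + nums:
        if name not in cohort.columns:
            raise ValidationError(f"predictor {name!r} not in cohort")

    data = cohort.copy()
    n_in = len(data)
    for c in cats:
        if c not in (
            *FORCED_REFERENCES,
        ):  # affiliation's unknown is a modeled level
            data = data.loc[data[c].astype(str) != "unknown"]
    for c in nums + [spec.response]:
        if c in data.columns:
            data = data.loc[data[c].notna()]
    meta: dict = {
        "design": spec.design,
        "n_input": n_in,
        "n_used": len(data),
        "n_dropped": n_in - len(data),
        "reference_levels": {},
        "scaling_bounds": {},
    }

    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    for c in cats:
        levels = data[c].astype(str)
        counts = levels.value_counts()
        if len(counts) < 2:
            raise ValidationError(
                f"categorical predictor {c!r} has a single level"
            )
        ref = spec.reference_levels.get(c, FORCED_REFERENCES.get(c))
        if ref is None:
            ref = counts.index[0]  # largest observed level
        if ref not in counts.index:
            raise ValidationError(
                f"reference level {ref!r} not observed for {c!r}"
            )
        meta["reference_levels"][c] = ref
        for level in sorted(l for l in counts.index if l != ref):
            X[f"{c}[{level}]"] = (levels == level).astype(float)
    for c in nums:
        v = data[c].to_numpy(dtype=float)
        lo, hi = float(np.min(v)), float(np.max(v))
        meta["scaling_bounds"][c] = (lo, hi)
        if spec.normalize_numeric:
            if hi == lo:
                raise ValidationError(f"numeric predictor {c!r} is constant")
            X[c] = (v - lo) / (hi - lo)
        else:
            X[c] = v
    return X, meta


def decode_design(X: pd.DataFrame, meta: dict) -> pd.DataFrame:
    """Recover categorical labels from a dummy block (round-trip check)."""
    out = pd.DataFrame(index=X.index)
    for factor, ref in meta["reference_levels"].items():
        cols = [c for c in X.columns if c.startswith(f"{factor}[")]
        labels = pd.Series(ref, index=X.index, dtype=object)
        for c in cols:
            level = c[len(factor) + 1 : -1]
            labels[X[c] == 1.0] = level
        out[factor] = labels
    return out


class ReductionRegression:
    """One of the three mobility-reduction regression designs."""

    def __init__(self, cohort: pd.DataFrame, spec: RegressionSpec | None = None):
        self.spec = spec or RegressionSpec()
        self.split = split_by_reduction(cohort)
        if self.spec.design in ("linear_positive", "loglinear_positive"):
            self.data = self.split.positive.copy()
            if self.data.empty:
                raise ValidationError("no users with positive reduction")
        else:
            self.data = pd.concat(
                [self.split.positive, self.split.nonpositive]
            ).copy()
            if (
                self.split.positive.empty
                or self.split.nonpositive.empty
            ):
                raise ValidationError(
                    "logistic design needs both outcome classes present"
                )

    @classmethod
    def from_cohort(
        cls, cohort: pd.DataFrame, design: str = "linear_positive", **kw
    ) -> "ReductionRegression":
        return cls(cohort, RegressionSpec(design=design, **kw))

    def fit(self) -> "ReductionRegressionResults":
        X, meta = encode_design(self.data, self.spec)
        rows = X.index
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # name the offending columns for the error message
            bad = []
            arr = X.to_numpy()
            base_rank = 0
            keep: list[int] = []
            for j in range(arr.shape[1]):
                r = np.linalg.matrix_rank(arr[:, keep + [j]])
                if r > base_rank:
                    keep.append(j)
                    base_rank = r
                else:
                    bad.append(X.columns[j])
            raise ValidationError(f"rank-deficient design; collinear: {bad}")

        if self.spec.design == "logistic_split":
            y = (
                self.data.loc[rows, "reduction"] > 0
            ).astype(float)
            if y.nunique() < 2:
                raise ValidationError("single-class outcome after encoding")
            fit = self._fit_logit(y, X)
        else:
            y = self.data.loc[rows, self.spec.response].to_numpy(dtype=float)
            if self.spec.design == "loglinear_positive":
                y = np.log1p(y)
            fit = sm.OLS(y, X).fit()
        return ReductionRegressionResults(self, fit, X, meta)

    @staticmethod
    def _fit_logit(y, X):
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels PerfectSeparationError etc.
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        # quasi-separation shows up as huge coefficients / non-convergence
        if not fit.mle_retvals.get("converged", True) or np.any(
            np.abs(fit.params) > 50
        ):
            raise SeparationError(
                "logistic fit did not converge (possible separation)"
            )
        return fit


class ReductionRegressionResults:
    """Coefficient table, fit metadata and summary for one design."""

    def __init__(self, model: ReductionRegression, fit, X, meta):
        self.model = model
        self._fit = fit
        self.design_matrix = X
        self.meta = meta
        self.params = pd.DataFrame(
            {
                "term": X.columns,
                "coef": np.asarray(fit.params, dtype=float),
                "std_error": np.asarray(fit.bse, dtype=float),
                "p": np.asarray(fit.pvalues, dtype=float),
            }
        )

    @property
    def n_used(self) -> int:
        return int(self.meta["n_used"])

    @property
    def converged(self) -> bool:
        retvals = getattr(self._fit, "mle_retvals", None)
        return bool(retvals.get("converged", True)) if retvals else True

    def coef(self, term: str) -> float:
        row = self.params.loc[self.params["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["coef"].iloc[0])

    def std_error(self, term: str) -> float:
        row = self.params.loc[self.params["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["std_error"].iloc[0])

    @property
    def resid(self):
        return np.asarray(self._fit.resid)

    @property
    def rsquared(self) -> float:
        return float(self._fit.rsquared)

    def summary(self) -> str:
        head = (
            f"Mobility reduction regression [{self.meta['design']}] "
            f"(n={self.n_used}, refs={self.meta['reference_levels']})"
        )
        return head + "\n\n" + self.params.to_string(
            index=False,
            formatters={
                "coef": "{:.4f}".format,
                "std_error": "{:.4f}".format,
                "p": "{:.3g}".format,
            },
        )
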