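"""Sensitivity analyses for the attributable-cost estimates.

Three checks on the primary attribution model:

* **Ladder bounds** — recompute the PAF under the sparsest model (age +
  health behaviours only) and the over-adjusted model (all mediators plus
  fragility).  Attribution typically shrinks as adjustment grows, so these
  bracket the primary estimate from above and below; the ordering is
  recorded, not enforced.
* **High-cost-user trim** — exclude the top 5% of health care users by
  total cost across all sectors and compare age-standardized cost ratios,
  guarding against a handful of extremely expensive respondents driving
  the estimates.
* **Inverse-probability-of-treatment weighting** — re-estimate exposure
  cost ratios by weighting each person by the inverse probability of their
  observed exposure level given covariates (stabilized by marginal level
  probabilities and truncated at a high percentile), an alternative
  adjustment route that should agree with the regression cost ratios when
  the model is correctly specified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from costpaf import attribution
from costpaf.cost_models import SECTORS, ModelSuite, PRIMARY_STEP
from costpaf.exposures import MISSING, VOCABULARY


@dataclass
class BoundedEstimate:
    """Primary PAF (ladder step 3) with step-1 upper / step-5 lower bounds.

    ``ordered`` records whether upper >= primary >= lower actually held.
    """

    primary: float
    upper: float
    lower: float

    @property
    def ordered(self) -> bool:
        return self.upper >= self.primary >= self.lower


def bound_estimates(
    suite: ModelSuite,
    cohort: pd.DataFrame,
    rule: attribution.RecodingRule,
    sector: str,
    *,
    weight_col: str = "weight",
) -> BoundedEstimate:
    """PAFs from ladder steps 1 (upper), 3 (primary) and 5 (lower)."""
    vals = {}
    for step in (1, PRIMARY_STEP, 5):
        models = suite.by_sex(sector, step)
        vals[step] = attribution.paf(models, cohort, rule, weight_col=weight_col)
    return BoundedEstimate(primary=vals[PRIMARY_STEP], upper=vals[1], lower=vals[5])


def total_cost(cohort: pd.DataFrame) -> pd.Series:
    """All-sector total cost over follow-up per person."""
    cols = [f"cost_{s}" for s in SECTORS if f"cost_{s}" in cohort.columns]
    if not cols:
        raise KeyError("cohort has no cost columns")
    return cohort[cols].sum(axis=1)


def exclude_top_users(
    cohort: pd.DataFrame, fraction: float = 0.05, *, id_col: str = "person_id"
) -> tuple[pd.DataFrame, dict]:
    """Drop the ceil(fraction * n) persons with highest total cost.

    Ties at the exclusion boundary are broken by stable person-id order
    (smallest ids removed first) with a warning.  Returns the retained
    subset and an exclusion report.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    totals = total_cost(cohort)
    n = len(cohort)
    k = ceil(fraction * n)
    order = (
        pd.DataFrame({"total": totals, "pid": cohort[id_col]})
        .sort_values(["total", "pid"], ascending=[False, True], kind="mergesort")
    )
    removed_idx = order.index[:k]
    threshold = float(order["total"].iloc[k - 1])
    tied = int((order["total"] == threshold).sum())
    if k < n and float(order["total"].iloc[k]) == threshold:
        warnings.warn(
            f"{tied} persons tie at the exclusion threshold {threshold}; "
            "ties broken by person id"
        )
    report = {
        "n": n,
        "n_removed": int(k),
        "fraction": fraction,
        "cost_threshold": threshold,
        "removed_ids": cohort.loc[removed_idx, id_col].tolist(),
    }
    return cohort.drop(index=removed_idx), report


def standard_population(
    cohort: pd.DataFrame, *, weight_col: str = "weight"
) -> dict[str, float]:
    """Survey-weighted age distribution of the full cohort (sums to 1)."""
    w = cohort.groupby("age_group")[weight_col].sum()
    return (w / w.sum()).to_dict()


def age_standardized_cost_ratio(
    cohort: pd.DataFrame,
    variable: str,
    exposure_level: str,
    reference_level: str,
    std: dict[str, float] | None = None,
    *,
    weight_col: str = "weight",
) -> float:
    """Directly age-standardized ratio of mean annualized costs.

    ratio = sum_a std(a) rbar_a(exposed) / sum_a std(a) rbar_a(reference)
    where rbar_a is the survey-weighted mean annualized total cost in age
    group a.  Age groups lacking either stratum are dropped from both sums
    symmetrically with a warning.
    """
    if std is None:
        std = standard_population(cohort, weight_col=weight_col)
    annualized = total_cost(cohort) / cohort["person_years"]
    df = pd.DataFrame({
        "age_group": cohort["age_group"],
        "level": cohort[variable],
        "w": cohort[weight_col],
        "cost": annualized,
    })
    num = den = 0.0
    dropped = []
    used = False
    for age, weight in std.items():
        grp = df[df["age_group"] == age]
        exp_grp = grp[grp["level"] == exposure_level]
        ref_grp = grp[grp["level"] == reference_level]
        if len(exp_grp) == 0 or len(ref_grp) == 0:
            dropped.append(age)
            continue
        used = True
        num += weight * np.average(exp_grp["cost"], weights=exp_grp["w"])
        den += weight * np.average(ref_grp["cost"], weights=ref_grp["w"])
    if dropped:
        warnings.warn(
            f"age groups {dropped} lack an exposed or reference stratum and "
            "were dropped from both sums"
        )
    if not used:
        raise ValueError(
            f"no age group contains both {exposure_level!r} and "
            f"{reference_level!r}"
        )
    if den == 0:
        raise ValueError("reference stratum has zero standardized cost")
    return float(num / den)


#: extra covariates entering the propensity model when present
IPW_EXTRA_COVARIATES = [
    "household_type", "household_education", "income_source",
    "labour_force", "belonging", "region", "cycle_year",
]


def ipw_cost_ratio(
    cohort: pd.DataFrame,
    treatment_variable: str,
    covariates: list[str],
    *,
    weight_col: str = "weight",
    truncate_percentile: float = 99.0,
    reference_level: str | None = None,
) -> pd.Series:
    """Inverse-probability-of-treatment-weighted cost ratios per level.

    Fits a multinomial logistic propensity model for the observed exposure
    level given the covariates, weights each person by the stabilized
    inverse probability of their observed level (marginal level probability
    over fitted propensity), truncates weights at ``truncate_percentile``,
    and returns the IPW survey-weighted mean annualized total cost of each
    level divided by the reference level's.
    """
    levels = VOCABULARY[treatment_variable]
    reference_level = reference_level or levels[0]
    sub = cohort[cohort[treatment_variable] != MISSING].copy()
    observed = [l for l in levels if (sub[treatment_variable] == l).any()]
    if reference_level not in observed:
        raise ValueError(f"reference level {reference_level!r} is empty")
    for level in observed:
        if (sub[treatment_variable] == level).sum() == 0:
            raise ValueError(f"treatment level {level!r} is empty")

    X = pd.get_dummies(
        sub[covariates].astype(str), drop_first=True, dtype=float
    )
    y = sub[treatment_variable].to_numpy()
    clf = LogisticRegression(
        C=1e4, max_iter=2000, solver="lbfgs", random_state=0
    )
    clf.fit(X.to_numpy(), y)
    proba = pd.DataFrame(
        clf.predict_proba(X.to_numpy()), columns=clf.classes_, index=sub.index
    )
    p_obs = np.array([proba.at[i, lev] for i, lev in zip(sub.index, y)])
    marginal = sub[treatment_variable].value_counts(normalize=True)
    stabilizer = marginal.loc[y].to_numpy()
    ipw = stabilizer / np.clip(p_obs, 1e-12, None)

    cap = np.percentile(ipw, truncate_percentile)
    n_trunc = int((ipw > cap).sum())
    if n_trunc:
        near_zero = int((p_obs < 1e-4).sum())
        if near_zero:
            warnings.warn(
                f"{near_zero} propensities near zero; {n_trunc} weights "
                f"truncated at the {truncate_percentile} percentile"
            )
    ipw = np.minimum(ipw, cap)

    annualized = (total_cost(sub) / sub["person_years"]).to_numpy()
    w = ipw * sub[weight_col].to_numpy(dtype=float)
    means = {}
    for level in observed:
        m = y == level
        means[level] = float(np.average(annualized[m], weights=w[m]))
    ref = means[reference_level]
    return pd.Series(
        {level: means[level] / ref for level in observed},
        name=f"ipw_cost_ratio_vs_{reference_level}",
    )


def crude_cost_ratio(
    cohort: pd.DataFrame,
    treatment_variable: str,
    *,
    weight_col: str = "weight",
    reference_level: str | None = None,
) -> pd.Series:
    """Unadjusted survey-weighted mean annualized cost ratios per level."""
    levels = VOCABULARY[treatment_variable]
    reference_level = reference_level or levels[0]
    sub = cohort[cohort[treatment_variable] != MISSING]
    annualized = (total_cost(sub) / sub["person_years"]).to_numpy()
    w = sub[weight_col].to_numpy(dtype=float)
    y = sub[treatment_variable].to_numpy()
    means = {
        level: float(np.average(annualized[y == level], weights=w[y == level]))
        for level in levels
        if (y == level).any()
    }
    ref = means[reference_level]
    return pd.Series(
        {level: v / ref for level, v in means.items()},
        name=f"crude_cost_ratio_vs_{reference_level}",
    )
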