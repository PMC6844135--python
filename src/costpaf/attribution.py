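"""Factor-deleted counterfactual population attributable fractions.

The PAF of a risk factor for a cost sector is computed by model-based
standardization (g-computation) in three steps: (1) predict expected annual
costs for the survey-weighted cohort under observed exposures; (2) repeat
after recoding the risk factor to its counterfactual reference ("no
exposure") category — e.g. all current and former smokers set to
non-smoker; (3) divide the difference by the original total:

    PAF = (sum_i w_i mu_i - sum_i w_i mu_i^0) / sum_i w_i mu_i

Predictions come from sex-specific models and are pooled across sexes
before the ratio, producing population-level PAFs.  Combined-behaviour PAFs
recode all four behaviours simultaneously; the socioeconomic "equity gap"
recodes education, income, home ownership and neighbourhood deprivation to
their lowest-cost levels.  Annual series between survey cycles are filled
by averaging the nearest preceding and succeeding cycle estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from costpaf.cost_models import FittedCostModel, predict_expected_cost
from costpaf.exposures import (
    BEHAVIOUR_VARIABLES,
    MISSING,
    REFERENCE_LEVELS,
    SES_VARIABLES,
)


@dataclass(frozen=True)
class RecodingRule:
    """Counterfactual assignment of target variables to reference levels.

    ``reference_assignment`` maps each target variable to the level it is
    set to; ``restrict_levels`` optionally limits recoding to a subset of
    levels (e.g. recode only heavy drinkers, leaving non-drinkers as
    observed).  Missing values are never recoded: an unknown exposure stays
    unknown rather than being asserted unexposed.
    """

    reference_assignment: Mapping[str, str]
    restrict_levels: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def target_variables(self) -> list[str]:
        return list(self.reference_assignment)


def behaviour_rule(variable: str) -> RecodingRule:
    """Single-behaviour rule sending the variable to its reference level."""
    if variable not in REFERENCE_LEVELS:
        raise KeyError(f"no reference level defined for {variable!r}")
    return RecodingRule({variable: REFERENCE_LEVELS[variable]})


def combined_behaviour_rule(*, alcohol_heavy_only: bool = False) -> RecodingRule:
    """All four behaviours to reference simultaneously.

    ``alcohol_heavy_only`` restricts the alcohol recoding to heavy drinkers
    (non-drinkers keep their observed category), avoiding negative alcohol
    components when non-drinkers cost more than moderate drinkers.
    """
    restrict = {"alcohol": ("heavy",)} if alcohol_heavy_only else {}
    return RecodingRule(
        {v: REFERENCE_LEVELS[v] for v in BEHAVIOUR_VARIABLES}, restrict
    )


def ses_rule() -> RecodingRule:
    """Equity-gap rule: everyone at the lowest-cost socioeconomic levels."""
    return RecodingRule({v: REFERENCE_LEVELS[v] for v in SES_VARIABLES})


def counterfactual_recode(cohort: pd.DataFrame, rule: RecodingRule) -> pd.DataFrame:
    """Copy of the cohort with rule targets set to their reference levels.

    Every non-reference, non-missing level of each target variable is set
    to the rule's reference level (or only the listed levels when the rule
    restricts); all other columns are untouched.
    """
    out = cohort.copy()
    for variable, reference in rule.reference_assignment.items():
        if variable not in out.columns:
            raise KeyError(f"unknown recoding target {variable!r}")
        values = out[variable]
        mask = values.notna() & (values != reference) & (values != MISSING)
        restrict = rule.restrict_levels.get(variable)
        if restrict is not None:
            mask &= values.isin(restrict)
        out.loc[mask, variable] = reference
    return out


def paf(
    models_by_sex: Mapping[str, FittedCostModel] | FittedCostModel,
    cohort: pd.DataFrame,
    rule: RecodingRule,
    *,
    weight_col: str = "weight",
) -> float:
    """Population attributable fraction for one sector.

    ``models_by_sex`` maps sex to that sex's fitted sector model (a single
    model may be passed for a single-sex cohort).  Predictions under the
    observed and the counterfactually recoded cohort are pooled across
    sexes before the ratio.  May be negative when the reference level is
    not cost-minimal for part of the population.
    """
    if isinstance(models_by_sex, FittedCostModel):
        models_by_sex = {models_by_sex.sex: models_by_sex}
    recoded = counterfactual_recode(cohort, rule)
    w = cohort[weight_col].to_numpy(dtype=float)
    mu = np.empty(len(cohort))
    mu0 = np.empty(len(cohort))
    seen = np.zeros(len(cohort), dtype=bool)
    for sex, model in models_by_sex.items():
        m = (cohort["sex"] == sex).to_numpy()
        if not m.any():
            continue
        mu[m] = predict_expected_cost(model, cohort[m]).to_numpy()
        mu0[m] = predict_expected_cost(model, recoded[m]).to_numpy()
        seen |= m
    if not seen.all():
        missing_sex = sorted(cohort.loc[~seen, "sex"].unique())
        raise ValueError(f"no model supplied for sex: {missing_sex}")
    total = float((w * mu).sum())
    if total <= 0:
        raise ValueError("total predicted cost is zero; PAF undefined")
    return float((w * mu - w * mu0).sum() / total)


def combined_paf(
    models_by_sex: Mapping[str, FittedCostModel] | FittedCostModel,
    cohort: pd.DataFrame,
    *,
    weight_col: str = "weight",
    alcohol_heavy_only: bool = False,
) -> float:
    """PAF from recoding all four behaviours to reference simultaneously."""
    return paf(
        models_by_sex, cohort,
        combined_behaviour_rule(alcohol_heavy_only=alcohol_heavy_only),
        weight_col=weight_col,
    )


CYCLE_ESTIMATE = "cycle_estimate"
INTERPOLATED = "interpolated"


def annual_paf_series(
    cycle_pafs: Mapping[int, float], years: range | list[int]
) -> pd.DataFrame:
    """Annual PAF series with between-cycle interpolation.

    Cycle years keep their estimate; each gap year gets the arithmetic mean
    of the nearest preceding and succeeding cycle estimates.  Years outside
    the span of the cycle estimates raise (no extrapolation).  Returns a
    tidy frame with columns year, paf, provenance.
    """
    if not cycle_pafs:
        raise ValueError("need at least one cycle PAF estimate")
    cyc = sorted(cycle_pafs)
    rows = []
    for year in years:
        if year in cycle_pafs:
            rows.append((year, float(cycle_pafs[year]), CYCLE_ESTIMATE))
            continue
        prev = [c for c in cyc if c < year]
        nxt = [c for c in cyc if c > year]
        if not prev or not nxt:
            raise ValueError(
                f"year {year} is outside the span of cycle estimates "
                f"[{cyc[0]}, {cyc[-1]}]; extrapolation is not supported"
            )
        value = 0.5 * (cycle_pafs[prev[-1]] + cycle_pafs[nxt[0]])
        rows.append((year, float(value), INTERPOLATED))
    return pd.DataFrame(rows, columns=["year", "paf", "provenance"])


def paf_series_table(
    entries: Mapping[tuple[str, str], Mapping[int, float]],
    years: range | list[int],
) -> pd.DataFrame:
    """Tidy PAF series over (risk, sector) keys.

    ``entries[(risk, sector)]`` maps cycle year to PAF.  Returns columns
    risk, sector, year, paf, provenance with gap years interpolated.
    """
    frames = []
    for (risk, sector), cycle_pafs in entries.items():
        f = annual_paf_series(cycle_pafs, years)
        f.insert(0, "sector", sector)
        f.insert(0, "risk", risk)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
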