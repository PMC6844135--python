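"""Sex- and sector-specific negative-binomial cost regressions.

Each model regresses a person's total sector cost over follow-up (rounded to
whole dollars so the NB count likelihood is well defined) on categorical
risk factors with a log link and a log person-years offset, so exponentiated
coefficients are annualized cost ratios versus the reference category.

Covariates enter through a pre-specified five-step nested ladder that moves
from health behaviours alone to an over-adjusted model including mediators:

1. health behaviours (age + smoking, alcohol, diet, activity)
2. + basic sociodemographics (immigrant status, education, marital status)
3. + further sociodemographics — the primary attribution model (income,
   home ownership, urban residence, neighbourhood deprivation, ethnicity,
   self-perceived stress, flu vaccination)
4. + distal mediators (BMI and diagnosed illness indicators)
5. + proximal mediator (fragility)

Fitting the ladder for both sexes and the three cost sectors (hospital,
drugs, community care) yields 15 models per sex, 30 in total.

Dispersion is estimated per model by profiling the NB log-likelihood in the
dispersion parameter around an IRLS fit of the regression coefficients
(variance mu + alpha mu^2).  Survey weights can optionally enter the fit as
a pseudo-likelihood; by default fits are unweighted and weights are used
only at the prediction/standardization stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

from costpaf.exposures import VOCABULARY

logger = logging.getLogger(__name__)

SECTORS = ["hospital", "drugs", "community"]
SEXES = ["male", "female"]
LADDER_STEPS = [1, 2, 3, 4, 5]

#: variables added at each ladder step (cumulative)
STEP_ADDITIONS: dict[int, list[str]] = {
    1: ["age_group", "smoking", "alcohol", "diet", "activity"],
    2: ["immigrant", "education", "marital"],
    3: ["income", "home_owned", "urban", "deprivation", "ethnicity",
        "stress", "flu_shot"],
    4: ["bmi", "hypertension", "diabetes", "heart_disease", "cancer",
        "stroke", "dementia"],
    5: ["fragility"],
}

STEP_NAMES = {
    1: "health_behaviour",
    2: "sociodemographic",
    3: "primary_attribution",
    4: "distal_mediator",
    5: "proximal_mediator",
}

PRIMARY_STEP = 3


class ConvergenceError(RuntimeError):
    """NB fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


def ladder_covariates(step: int) -> list[str]:
    """Cumulative covariate list for a ladder step (nested in the next)."""
    if step not in STEP_ADDITIONS:
        raise ValueError(f"ladder step must be in 1..5, got {step}")
    out: list[str] = []
    for s in range(1, step + 1):
        out.extend(STEP_ADDITIONS[s])
    return out


@dataclass
class DesignInfo:
    """Categorical design description: variables, level orders, exclusions.

    ``levels[v]`` lists the levels of variable ``v`` with the reference
    level first; dummy columns are named ``"v[level]"`` for each
    non-reference level present in the estimation data.  Degenerate
    (zero-variance) dummies are excluded and recorded.
    """

    variables: list[str]
    levels: dict[str, list[str]]
    columns: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def reference_level(self, variable: str) -> str:
        return self.levels[variable][0]


def build_design(cohort: pd.DataFrame, step: int) -> DesignInfo:
    """Describe the categorical design for a ladder step on a cohort.

    Raises ``KeyError`` naming any absent covariate column.  Dummy columns
    that would be constant on this cohort (an all-reference variable, or a
    level nobody occupies) are flagged degenerate and excluded with a log
    record.
    """
    variables = ladder_covariates(step)
    missing_cols = [v for v in variables if v not in cohort.columns]
    if missing_cols:
        raise KeyError(
            f"cohort is missing categorized covariate columns: {missing_cols}"
        )
    levels = {v: list(VOCABULARY[v]) for v in variables}
    info = DesignInfo(variables=variables, levels=levels)
    for v in variables:
        observed = set(cohort[v].unique())
        unknown = observed - set(levels[v]) - {np.nan}
        if unknown:
            raise ValueError(f"column {v!r} has unknown levels {sorted(unknown)}")
        for level in levels[v][1:]:
            col = f"{v}[{level}]"
            count = int((cohort[v] == level).sum())
            if count == 0 or count == len(cohort):
                info.dropped.append(col)
                logger.info("design step %d: dropping degenerate column %s", step, col)
            else:
                info.columns.append(col)
    return info


def design_matrix(cohort: pd.DataFrame, info: DesignInfo, *, strict: bool = True
                  ) -> pd.DataFrame:
    """Expand a cohort to the dummy matrix described by ``info``.

    ``strict`` raises on factor levels never seen at fit time (excluded
    degenerate levels), naming the level, instead of silently predicting
    from a reference row.
    """
    X = pd.DataFrame(index=cohort.index)
    X["Intercept"] = 1.0
    active = set(info.columns)
    for v in info.variables:
        values = cohort[v]
        for level in info.levels[v][1:]:
            col = f"{v}[{level}]"
            ind = (values == level).to_numpy(dtype=float)
            if col in active:
                X[col] = ind
            elif strict and ind.any():
                raise ValueError(
                    f"level {level!r} of {v!r} was not estimable at fit time "
                    "but appears in the prediction cohort"
                )
    return X


@dataclass
class FittedCostModel:
    """One (sex, sector, ladder step) negative-binomial cost GLM.

    ``coefficients`` maps dummy-column names (plus ``"Intercept"``) to log
    cost ratios; ``dispersion`` is the NB2 alpha (variance mu + alpha mu^2);
    the offset convention is log person-years, so predictions are annual.
    """

    sex: str
    sector: str
    step: int
    coefficients: dict[str, float]
    dispersion: float
    design: DesignInfo
    standard_errors: dict[str, float] = field(default_factory=dict)
    loglike: float = float("nan")
    n_obs: int = 0
    converged: bool = True
    offset_convention: str = "log_person_years"

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coefficients)

    def cost_ratio(self, column: str) -> float:
        """Exponentiated coefficient: annual cost ratio vs the reference."""
        return float(np.exp(self.coefficients[column]))

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "sector": self.sector,
            "step": self.step,
            "coefficients": self.coefficients,
            "dispersion": self.dispersion,
            "standard_errors": self.standard_errors,
            "loglike": self.loglike,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "offset_convention": self.offset_convention,
            "design": {
                "variables": self.design.variables,
                "levels": self.design.levels,
                "columns": self.design.columns,
                "dropped": self.design.dropped,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedCostModel":
        design = DesignInfo(**d["design"])
        return cls(
            sex=d["sex"], sector=d["sector"], step=d["step"],
            coefficients=d["coefficients"], dispersion=d["dispersion"],
            design=design, standard_errors=d.get("standard_errors", {}),
            loglike=d.get("loglike", float("nan")), n_obs=d.get("n_obs", 0),
            converged=d.get("converged", True),
            offset_convention=d.get("offset_convention", "log_person_years"),
        )


def _nb_loglike(y: np.ndarray, mu: np.ndarray, alpha: float,
                weights: np.ndarray | None = None) -> float:
    """NB2 log-likelihood (optionally weight-summed)."""
    size = 1.0 / alpha
    ll = (
        special.gammaln(y + size) - special.gammaln(size) - special.gammaln(y + 1)
        + size * np.log(size) + y * np.log(mu)
        - (size + y) * np.log(size + mu)
    )
    if weights is not None:
        ll = ll * weights
    return float(ll.sum())


def _profile_alpha(y, mu, weights, lo=1e-6, hi=1e3) -> float:
    res = optimize.minimize_scalar(
        lambda la: -_nb_loglike(y, mu, np.exp(la), weights),
        bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def fit_cost_model(
    cohort: pd.DataFrame,
    sex: str,
    sector: str,
    step: int,
    *,
    weighted: bool = False,
    weight_col: str = "weight",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FittedCostModel:
    """Fit one NB cost GLM with log person-years offset.

    The cohort is restricted to ``sex``; outcome is ``cost_<sector>``
    rounded to whole dollars; offset is log(person_years).  Coefficients
    are updated by IRLS at fixed dispersion and the dispersion by scalar
    profile likelihood, alternating until the relative deviance change
    drops below ``tol``.  ``weighted`` enables survey-weight
    pseudo-likelihood fitting.
    """
    sub = cohort[cohort["sex"] == sex]
    if len(sub) == 0:
        raise ValueError(f"cohort contains no rows for sex={sex!r}")
    cost_col = f"cost_{sector}"
    if cost_col not in sub.columns:
        raise KeyError(f"cohort lacks cost column {cost_col!r}")
    y = np.round(sub[cost_col].to_numpy(dtype=float))
    if (y < 0).any():
        raise ValueError(f"{cost_col} contains negative costs")
    if not (y > 0).any():
        raise ValueError(f"{cost_col} is identically zero for sex={sex!r}")
    py = sub["person_years"].to_numpy(dtype=float)
    if (py <= 0).any():
        raise ValueError("person_years must be strictly positive")
    offset = np.log(py)
    weights = None
    if weighted:
        weights = sub[weight_col].to_numpy(dtype=float)
        if (weights <= 0).any():
            raise ValueError("survey weights must be strictly positive")

    info = build_design(sub, step)
    X = design_matrix(sub, info)

    # moment start for alpha from a Poisson fit
    pois = sm.GLM(
        y, X, family=sm.families.Poisson(), offset=offset, var_weights=weights
    ).fit()
    mu = np.clip(pois.mu, 1e-8, None)
    resid2 = (y - mu) ** 2 - mu
    denom = float((mu**2).sum())
    alpha = float(np.clip(resid2.sum() / denom if denom > 0 else 1.0, 1e-6, 1e3))

    # inner IRLS converges the coefficients at fixed alpha (relative
    # deviance tolerance `tol`); the outer loop converges alpha itself,
    # stopping once its profile update is numerically stationary
    trace: list[dict] = []
    res = pois
    for it in range(max_iter):
        fam = sm.families.NegativeBinomial(alpha=alpha)
        res = sm.GLM(y, X, family=fam, offset=offset, var_weights=weights).fit(
            maxiter=200, tol=tol, start_params=res.params
        )
        mu = np.clip(res.mu, 1e-12, None)
        new_alpha = _profile_alpha(y, mu, weights)
        trace.append(
            {"iteration": it, "alpha": alpha, "deviance": float(res.deviance)}
        )
        alpha_rel = abs(new_alpha - alpha) / (alpha + 1e-12)
        alpha = new_alpha
        if alpha_rel < 1e-5:
            break
    else:
        raise ConvergenceError(
            f"NB fit did not converge for ({sex}, {sector}, step {step})", trace
        )

    coeffs = dict(zip(X.columns, np.asarray(res.params, dtype=float)))
    ses = dict(zip(X.columns, np.asarray(res.bse, dtype=float)))
    return FittedCostModel(
        sex=sex, sector=sector, step=step,
        coefficients=coeffs, dispersion=alpha, design=info,
        standard_errors=ses,
        loglike=_nb_loglike(y, mu, alpha, weights),
        n_obs=len(sub), converged=True,
    )


def predict_expected_cost(model: FittedCostModel, cohort: pd.DataFrame
                          ) -> pd.Series:
    """Per-person expected *annual* sector cost exp(x'beta).

    The person-years offset contribution is removed, i.e. predictions are
    per person-year; multiply by person-years for follow-up totals.
    """
    X = design_matrix(cohort, model.design, strict=True)
    beta = pd.Series(model.coefficients).reindex(X.columns)
    if beta.isna().any():
        raise ValueError("design/coefficient mismatch")
    eta = X.to_numpy() @ beta.to_numpy()
    return pd.Series(np.exp(eta), index=cohort.index, name=f"mu_{model.sector}")


@dataclass
class ModelSuite:
    """All fitted models keyed by (sex, sector, ladder step)."""

    models: dict[tuple[str, str, int], FittedCostModel] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, str, int]) -> FittedCostModel:
        return self.models[key]

    def get(self, sex: str, sector: str, step: int) -> FittedCostModel:
        key = (sex, sector, step)
        if key not in self.models:
            raise KeyError(f"no fitted model for sex={sex}, sector={sector}, step={step}")
        return self.models[key]

    def by_sex(self, sector: str, step: int) -> dict[str, FittedCostModel]:
        return {sex: self.get(sex, sector, step) for sex in SEXES}

    def count(self, sex: str | None = None) -> int:
        if sex is None:
            return len(self.models)
        return sum(1 for (s, _, _) in self.models if s == sex)

    def to_json(self, path) -> None:
        payload = [m.to_dict() for m in self.models.values()]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelSuite":
        with open(path) as fh:
            payload = json.load(fh)
        suite = cls()
        for d in payload:
            m = FittedCostModel.from_dict(d)
            suite.models[(m.sex, m.sector, m.step)] = m
        return suite


def fit_model_suite(
    cohort: pd.DataFrame,
    *,
    steps: list[int] | None = None,
    sectors: list[str] | None = None,
    weighted: bool = False,
) -> ModelSuite:
    """Fit the full sex x sector x ladder-step grid of cost models.

    With all five steps and three sectors this is 15 models per sex,
    30 in total.  Errors are re-raised with (sex, sector, step) context.
    """
    steps = steps or LADDER_STEPS
    sectors = sectors or SECTORS
    present = set(cohort["sex"].unique())
    absent = [s for s in SEXES if s not in present]
    if absent:
        raise ValueError(f"cohort lacks rows for sex: {absent}")
    suite = ModelSuite()
    for sex in SEXES:
        for sector in sectors:
            for step in steps:
                try:
                    suite.models[(sex, sector, step)] = fit_cost_model(
                        cohort, sex, sector, step, weighted=weighted
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"cost model fit failed for sex={sex}, sector={sector}, "
                        f"step={step}: {exc}"
                    ) from exc
    return suite
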