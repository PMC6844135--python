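"""Synthetic multi-cycle survey cohorts with known cost-generating truth.

The generator emulates the structure of repeated cross-sectional health
survey cycles linked to administrative cost records: per-cycle samples with
survey weights, 1-4 years of follow-up, raw behaviour responses (smoking
amounts, weekly drinks and bingeing, fruit/vegetable servings, leisure
activity sessions), socioeconomic and health-status covariates, and
per-sector costs drawn from a log-link negative-binomial model with known
coefficients.  Behaviour prevalences drift linearly across cycles (notably
declining heavy smoking) and depend on socioeconomic position through a
configurable log-odds tilt, giving designed confounding.

Raw responses are synthesized *from* the sampled exposure category so that
the deterministic categorizers in :mod:`costpaf.exposures` recover the
intended category exactly (round-trip property), except where missingness
is injected.

Ground-truth PAFs of the generating model are computed by exact enumeration
over the discrete covariate distribution — no sampling error — so every
pipeline stage can be checked against truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from costpaf import exposures
from costpaf.burden import BASE_YEAR, CpiSeries, ExpenditureTable
from costpaf.exposures import AGE_GROUPS, BEHAVIOUR_VARIABLES, REFERENCE_LEVELS

SECTORS = ["hospital", "drugs", "community"]

#: relative "riskiness" of each behaviour level, used to tilt prevalences
#: by socioeconomic group (confounding) — higher means more common among
#: the disadvantaged group
RISK_WEIGHT = {
    "smoking": {"heavy": 1.0, "light": 0.5, "former_heavy": 0.3,
                "former_light": 0.2, "non": 0.0},
    "alcohol": {"heavy": 1.0, "non": 0.3, "moderate": 0.0},
    "diet": {"poor": 1.0, "fair": 0.5, "adequate": 0.0},
    "activity": {"inactive": 1.0, "moderate": 0.5, "active": 0.0},
}

SES_DIRECTION = {"postsecondary": -1.0, "highschool": 0.0, "lt_highschool": 1.0}


class GeneratorConfig(BaseModel):
    """Generating parameters for the synthetic survey cohorts.

    ``behaviour_prevalence[b][level] = (p_first, p_last)`` interpolates
    linearly between the first and last cycle year; each endpoint vector
    must sum to 1.  ``coefficients[sector][variable][level]`` are true log
    annual-cost ratios; ``baseline_annual_cost`` the reference-person
    annual cost in 2014 dollars; ``dispersion`` the NB2 alpha per sector.
    ``confounding_strength`` is the log-odds tilt applied to risky
    behaviour levels for the low-education group (and its negative for the
    post-secondary group).
    """

    model_config = ConfigDict(extra="forbid")

    n_per_cycle: int = 20_000
    cycle_years: list[int] = [2003, 2005, 2007, 2009, 2011, 2013]
    linked_cycle_years: list[int] = [2003, 2005, 2007]
    sex_mix: dict[str, float] = {"male": 0.46, "female": 0.54}
    age_distribution: list[float] = [
        0.074, 0.090, 0.103, 0.111, 0.090, 0.096, 0.100,
        0.090, 0.079, 0.068, 0.053, 0.031, 0.012, 0.003,
    ]
    behaviour_prevalence: dict[str, dict[str, tuple[float, float]]] = {
        # heavy smoking declines markedly over the decade; quitters accrue
        "smoking": {
            "heavy": (0.11, 0.06), "light": (0.14, 0.11),
            "former_heavy": (0.15, 0.17), "former_light": (0.17, 0.19),
            "non": (0.43, 0.47),
        },
        "alcohol": {
            "heavy": (0.09, 0.08), "moderate": (0.71, 0.72),
            "non": (0.20, 0.20),
        },
        "diet": {
            "poor": (0.12, 0.11), "fair": (0.36, 0.35),
            "adequate": (0.52, 0.54),
        },
        "activity": {
            "inactive": (0.50, 0.47), "moderate": (0.25, 0.26),
            "active": (0.25, 0.27),
        },
    }
    ses_prevalence: dict[str, dict[str, float]] = {
        "education": {"postsecondary": 0.56, "highschool": 0.24,
                      "lt_highschool": 0.20},
        "income": {"ge80k": 0.30, "30to80k": 0.44, "lt30k": 0.26},
        "home_owned": {"yes": 0.78, "no": 0.22},
        "deprivation": {"low": 0.20, "moderate": 0.64, "high": 0.16},
    }
    covariate_prevalence: dict[str, dict[str, float]] = {
        "immigrant": {"no": 0.78, "yes": 0.22},
        "marital": {"married": 0.63, "other": 0.37},
        "urban": {"yes": 0.78, "no": 0.22},
        "ethnicity": {"white": 0.89, "nonwhite": 0.11},
        "stress": {"low": 0.79, "high": 0.21},
        "flu_shot": {"no": 0.35, "yes": 0.65},
        "bmi": {"normal": 0.40, "underweight": 0.02, "overweight": 0.33,
                "obese": 0.18, "morbidly_obese": 0.07},
        "hypertension": {"no": 0.76, "yes": 0.24},
        "diabetes": {"no": 0.92, "yes": 0.08},
        "heart_disease": {"no": 0.91, "yes": 0.09},
        "cancer": {"no": 0.97, "yes": 0.03},
        "stroke": {"no": 0.98, "yes": 0.02},
        "dementia": {"no": 0.995, "yes": 0.005},
        "fragility": {"none": 0.69, "limitation": 0.21, "needs_help": 0.10},
    }
    confounding_strength: float = 0.3
    baseline_annual_cost: dict[str, float] = {
        "hospital": 1200.0, "drugs": 500.0, "community": 800.0,
    }
    dispersion: dict[str, float] = {
        "hospital": 1.2, "drugs": 0.9, "community": 0.7,
    }
    #: true log annual-cost ratios per sector; variables not listed have no
    #: effect in the generating model
    coefficients: dict[str, dict[str, dict[str, float]]] = {
        "hospital": {
            "smoking": {"heavy": 0.40, "light": 0.15, "former_heavy": 0.20,
                        "former_light": 0.08},
            "alcohol": {"heavy": 0.10, "non": 0.15},
            "diet": {"poor": 0.25, "fair": 0.10},
            "activity": {"inactive": 0.35, "moderate": 0.12},
            "education": {"highschool": 0.05, "lt_highschool": 0.15},
            "deprivation": {"moderate": 0.05, "high": 0.12},
        },
        "drugs": {
            "smoking": {"heavy": 0.30, "light": 0.12, "former_heavy": 0.15,
                        "former_light": 0.06},
            "alcohol": {"heavy": 0.05, "non": 0.10},
            "diet": {"poor": 0.20, "fair": 0.08},
            "activity": {"inactive": 0.28, "moderate": 0.10},
            "education": {"highschool": 0.04, "lt_highschool": 0.12},
            "deprivation": {"moderate": 0.04, "high": 0.10},
        },
        "community": {
            "smoking": {"heavy": 0.25, "light": 0.10, "former_heavy": 0.12,
                        "former_light": 0.05},
            "alcohol": {"heavy": 0.06, "non": 0.08},
            "diet": {"poor": 0.15, "fair": 0.06},
            "activity": {"inactive": 0.22, "moderate": 0.08},
            "education": {"highschool": 0.03, "lt_highschool": 0.10},
            "deprivation": {"moderate": 0.03, "high": 0.08},
        },
    }
    #: per-age-group log cost ratio increment (linear age gradient)
    age_gradient: dict[str, float] = {
        "hospital": 0.10, "drugs": 0.14, "community": 0.06,
    }
    weight_log_mean: float = float(np.log(100.0))
    weight_log_sd: float = 0.5
    followup_probs: dict[int, float] = {1: 0.05, 2: 0.05, 3: 0.10, 4: 0.80}
    missingness: dict[str, float] = {
        "smoking": 0.01, "alcohol": 0.015, "diet": 0.04, "activity": 0.015,
    }
    other_share: float = 0.20
    cpi_annual_inflation: float = 0.018
    population_size: float = 2_000_000.0

    @field_validator("behaviour_prevalence")
    @classmethod
    def _prevalences_sum_to_one(cls, v):
        for b, levels in v.items():
            for j, end in enumerate(["first", "last"]):
                s = sum(p[j] for p in levels.values())
                if abs(s - 1.0) > 1e-9:
                    raise ValueError(
                        f"{b} {end}-cycle prevalences sum to {s}, expected 1"
                    )
        return v

    @field_validator("followup_probs")
    @classmethod
    def _followup_valid(cls, v):
        if set(v) - {1, 2, 3, 4}:
            raise ValueError("follow-up is limited to 1..4 years")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("follow-up probabilities must sum to 1")
        return v

    def year_fraction(self, year: int) -> float:
        y0, y1 = self.cycle_years[0], self.cycle_years[-1]
        if y1 == y0:
            return 0.0
        return (year - y0) / (y1 - y0)


def behaviour_prevalence_at(
    config: GeneratorConfig, behaviour: str, year: int, education: str
) -> dict[str, float]:
    """Level probabilities for a behaviour in a year and education group.

    Linear interpolation between first- and last-cycle prevalences, then a
    multiplicative exp(confounding x risk-weight x SES-direction) tilt,
    renormalized.
    """
    t = config.year_fraction(year)
    base = {
        level: (1 - t) * p0 + t * p1
        for level, (p0, p1) in config.behaviour_prevalence[behaviour].items()
    }
    c = config.confounding_strength * SES_DIRECTION[education]
    tilted = {
        level: p * np.exp(c * RISK_WEIGHT[behaviour][level])
        for level, p in base.items()
    }
    total = sum(tilted.values())
    return {level: p / total for level, p in tilted.items()}


def _sector_log_ratio(config: GeneratorConfig, sector: str, variable: str,
                      level: str) -> float:
    if variable == "age_group":
        return config.age_gradient[sector] * AGE_GROUPS.index(level)
    return config.coefficients[sector].get(variable, {}).get(level, 0.0)


def true_annual_cost(config: GeneratorConfig, sector: str,
                     levels: dict[str, str]) -> float:
    """Generating-model expected annual cost for one covariate cell."""
    eta = np.log(config.baseline_annual_cost[sector])
    for variable, level in levels.items():
        eta += _sector_log_ratio(config, sector, variable, level)
    return float(np.exp(eta))


# --- raw-response synthesis ----------------------------------------------

def _raw_smoking(category: str, rng: np.random.Generator) -> dict:
    if category == "heavy":
        return {"smoking_status": "current_daily",
                "cigs_per_day": float(rng.integers(20, 41)),
                "lifetime_cigs_ge_100": True}
    if category == "light":
        if rng.random() < 0.3:
            return {"smoking_status": "current_occasional",
                    "cigs_per_day": np.nan, "lifetime_cigs_ge_100": True}
        return {"smoking_status": "current_daily",
                "cigs_per_day": float(rng.integers(1, 20)),
                "lifetime_cigs_ge_100": True}
    if category == "former_heavy":
        return {"smoking_status": "former_daily",
                "cigs_per_day": float(rng.integers(20, 41)),
                "lifetime_cigs_ge_100": True}
    if category == "former_light":
        if rng.random() < 0.3:
            return {"smoking_status": "former_occasional",
                    "cigs_per_day": np.nan, "lifetime_cigs_ge_100": True}
        return {"smoking_status": "former_daily",
                "cigs_per_day": float(rng.integers(1, 20)),
                "lifetime_cigs_ge_100": True}
    if category == "non":
        if rng.random() < 0.2:
            return {"smoking_status": "current_occasional",
                    "cigs_per_day": np.nan, "lifetime_cigs_ge_100": False}
        return {"smoking_status": "never", "cigs_per_day": np.nan,
                "lifetime_cigs_ge_100": False}
    raise ValueError(category)


def _raw_alcohol(category: str, sex: str, rng: np.random.Generator) -> dict:
    threshold = exposures.DRINK_THRESHOLD[sex]
    if category == "heavy":
        if rng.random() < 0.5:
            return {"drinks_per_week": float(rng.uniform(0, threshold)),
                    "binge_any_day_prev_week": True,
                    "weekly_binge_prev_month": bool(rng.random() < 0.4),
                    "any_alcohol_12mo": True}
        return {"drinks_per_week": float(rng.uniform(threshold + 0.5,
                                                     threshold + 20)),
                "binge_any_day_prev_week": False,
                "weekly_binge_prev_month": False,
                "any_alcohol_12mo": True}
    if category == "moderate":
        return {"drinks_per_week": float(rng.uniform(0.5, threshold)),
                "binge_any_day_prev_week": False,
                "weekly_binge_prev_month": False,
                "any_alcohol_12mo": True}
    if category == "non":
        return {"drinks_per_week": 0.0, "binge_any_day_prev_week": False,
                "weekly_binge_prev_month": False, "any_alcohol_12mo": False}
    raise ValueError(category)


def _raw_diet(category: str, rng: np.random.Generator) -> dict:
    # score = 2 + fv with no deductions; ranges chosen to land in-category
    if category == "poor":
        fv = rng.uniform(0.0, 0.45)
    elif category == "fair":
        fv = rng.uniform(0.55, 2.95)
    elif category == "adequate":
        fv = rng.uniform(3.05, 8.0)
    else:
        raise ValueError(category)
    return {"fv_servings": float(fv), "juice_servings": float(rng.uniform(0, 1)),
            "carrot_consumed": True, "potato_servings": float(rng.uniform(0, 0.6))}


def _raw_activity(category: str, rng: np.random.Generator) -> dict:
    if category == "inactive":
        met = rng.uniform(0.0, 1.45)
    elif category == "moderate":
        met = rng.uniform(1.55, 2.95)
    elif category == "active":
        met = rng.uniform(3.05, 6.0)
    else:
        raise ValueError(category)
    return {"activity_sessions_per_week": 7.0,
            "activity_hours_per_session": float(met / 3.0),
            "activity_met_value": 3.0}


_DEPRIVATION_CELLS = {
    "low": [(m, s) for m in (1, 2) for s in (1, 2)],
    "high": [(m, s) for m in (4, 5) for s in (4, 5)],
    "moderate": [
        (m, s) for m in range(1, 6) for s in range(1, 6)
        if not (m <= 2 and s <= 2) and not (m >= 4 and s >= 4)
    ],
}


def _raw_deprivation(category: str, rng: np.random.Generator) -> dict:
    cells = _DEPRIVATION_CELLS[category]
    m, s = cells[rng.integers(len(cells))]
    return {"material_quintile": m, "social_quintile": s}


_MISSING_FIELDS = {
    "smoking": ["smoking_status", "cigs_per_day", "lifetime_cigs_ge_100"],
    "alcohol": ["drinks_per_week", "binge_any_day_prev_week",
                "weekly_binge_prev_month", "any_alcohol_12mo"],
    "diet": ["fv_servings", "juice_servings", "carrot_consumed",
             "potato_servings"],
    "activity": ["activity_sessions_per_week", "activity_hours_per_session",
                 "activity_met_value"],
}


def _sample_levels(rng, levels, probs, n):
    idx = rng.choice(len(levels), size=n, p=probs)
    return np.array(levels, dtype=object)[idx]


def generate_cycle(
    config: GeneratorConfig, year: int, rng: np.random.Generator,
    *, with_costs: bool = True, id_offset: int = 0
) -> pd.DataFrame:
    """One survey cycle: covariates, raw responses, weights, follow-up, costs."""
    n = config.n_per_cycle
    rows: dict[str, np.ndarray | list] = {}
    rows["person_id"] = np.arange(id_offset, id_offset + n)
    rows["cycle_year"] = np.full(n, year)
    sexes = list(config.sex_mix)
    rows["sex"] = _sample_levels(rng, sexes, [config.sex_mix[s] for s in sexes], n)
    rows["age_group"] = _sample_levels(rng, AGE_GROUPS, config.age_distribution, n)

    edu_levels = list(config.ses_prevalence["education"])
    edu_probs = list(config.ses_prevalence["education"].values())
    education = _sample_levels(rng, edu_levels, edu_probs, n)
    rows["education"] = education

    for var in ("income", "home_owned"):
        levels = list(config.ses_prevalence[var])
        rows[var] = _sample_levels(
            rng, levels, list(config.ses_prevalence[var].values()), n
        )
    dep_levels = list(config.ses_prevalence["deprivation"])
    dep_cat = _sample_levels(
        rng, dep_levels, list(config.ses_prevalence["deprivation"].values()), n
    )
    for var, levels in config.covariate_prevalence.items():
        rows[var] = _sample_levels(rng, list(levels), list(levels.values()), n)

    # behaviours conditional on education (the confounding mechanism)
    true_cats = {}
    for behaviour in BEHAVIOUR_VARIABLES:
        cats = np.empty(n, dtype=object)
        for edu in edu_levels:
            p = behaviour_prevalence_at(config, behaviour, year, edu)
            m = education == edu
            cats[m] = _sample_levels(rng, list(p), list(p.values()), int(m.sum()))
        true_cats[behaviour] = cats
        rows[f"true_{behaviour}"] = cats

    # raw responses consistent with the sampled categories
    raw_records: dict[str, list] = {}
    synthesizers = {
        "smoking": lambda c, s: _raw_smoking(c, rng),
        "alcohol": lambda c, s: _raw_alcohol(c, s, rng),
        "diet": lambda c, s: _raw_diet(c, rng),
        "activity": lambda c, s: _raw_activity(c, rng),
    }
    for behaviour, synth in synthesizers.items():
        recs = [synth(true_cats[behaviour][i], rows["sex"][i]) for i in range(n)]
        for key in recs[0]:
            raw_records[key] = [r[key] for r in recs]
    dep_recs = [_raw_deprivation(c, rng) for c in dep_cat]
    raw_records["material_quintile"] = [r["material_quintile"] for r in dep_recs]
    raw_records["social_quintile"] = [r["social_quintile"] for r in dep_recs]
    rows.update({k: np.asarray(v, dtype=object) for k, v in raw_records.items()})
    rows["true_deprivation"] = dep_cat

    rows["weight"] = rng.lognormal(config.weight_log_mean, config.weight_log_sd, n)
    fu_years = np.array(sorted(config.followup_probs))
    fu_probs = [config.followup_probs[y] for y in fu_years]
    rows["person_years"] = rng.choice(fu_years, size=n, p=fu_probs).astype(float)

    df = pd.DataFrame(rows)

    if with_costs:
        for sector in SECTORS:
            eta = np.full(n, np.log(config.baseline_annual_cost[sector]))
            age_idx = np.array([AGE_GROUPS.index(a) for a in df["age_group"]])
            eta += config.age_gradient[sector] * age_idx
            for variable in config.coefficients[sector]:
                col = (f"true_{variable}" if variable in BEHAVIOUR_VARIABLES
                       else variable)
                source = df["true_deprivation"] if variable == "deprivation" else df[col]
                coefs = config.coefficients[sector][variable]
                eta += np.array([coefs.get(l, 0.0) for l in source])
            mean = np.exp(eta) * df["person_years"].to_numpy()
            alpha = config.dispersion[sector]
            lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
            df[f"cost_{sector}"] = rng.poisson(lam).astype(float)

    # inject missingness into raw behaviour responses
    for behaviour, rate in config.missingness.items():
        if rate <= 0:
            continue
        mask = rng.random(n) < rate
        for field_name in _MISSING_FIELDS[behaviour]:
            df.loc[mask, field_name] = np.nan
    return df


def generate_cohort(
    config: GeneratorConfig, seed: int, *, cycles: list[int] | None = None,
    with_costs: bool = True,
) -> pd.DataFrame:
    """Multi-cycle cohort table, scored with the exposure categorizers.

    Reproducible given the seed.  Includes the ``true_*`` sampled
    categories alongside the categorized observed columns (which differ
    only where missingness was injected).
    """
    cycles = cycles if cycles is not None else config.cycle_years
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for year in config.cycle_years:
        cyc = generate_cycle(config, year, rng, with_costs=with_costs,
                             id_offset=offset)
        offset += len(cyc)
        if year in cycles:
            frames.append(cyc)
    df = pd.concat(frames, ignore_index=True)
    return exposures.score_cohort(df)


def generate_linked_cohort(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """The cost-linked fitting cohort (linked cycles only, with costs)."""
    return generate_cohort(config, seed, cycles=config.linked_cycle_years)


# --- ground truth ---------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact generating-model PAFs and cost ratios.

    ``paf[(risk, sector, year)]`` holds the enumerated PAF for the
    single-behaviour rules, ``"combined"`` and ``"ses"``.
    """

    paf: dict[tuple[str, str, int], float]
    cost_ratios: dict[str, dict[str, dict[str, float]]]
    combined_paf: dict[tuple[str, int], float] = field(default_factory=dict)

    def series(self, risk: str, sector: str) -> dict[int, float]:
        return {
            year: v for (r, s, year), v in self.paf.items()
            if r == risk and s == sector
        }


def _enumerate_cells(config: GeneratorConfig, year: int) -> pd.DataFrame:
    """Joint distribution over the covariates with nonzero coefficients."""
    edu = config.ses_prevalence["education"]
    dep = config.ses_prevalence["deprivation"]
    behaviour_levels = {
        b: list(config.behaviour_prevalence[b]) for b in BEHAVIOUR_VARIABLES
    }
    records = []
    for age_i, age_p in enumerate(config.age_distribution):
        age = AGE_GROUPS[age_i]
        for e, ep in edu.items():
            cond = {
                b: behaviour_prevalence_at(config, b, year, e)
                for b in BEHAVIOUR_VARIABLES
            }
            for d, dp in dep.items():
                base_p = age_p * ep * dp
                for combo in itertools.product(
                    *(behaviour_levels[b] for b in BEHAVIOUR_VARIABLES)
                ):
                    p = base_p
                    levels = {"age_group": age, "education": e, "deprivation": d}
                    for b, level in zip(BEHAVIOUR_VARIABLES, combo):
                        p *= cond[b][level]
                        levels[b] = level
                    records.append({**levels, "p": p})
    return pd.DataFrame(records)


def true_paf(config: GeneratorConfig, *, years: list[int] | None = None
             ) -> GroundTruth:
    """Exact PAFs of the generating model by enumeration over cells.

    For each (risk, sector, year): PAF = (sum p mu - sum p mu0) / sum p mu
    over the discrete joint covariate distribution.  Counterfactual means
    account for injected missingness: with missingness rate r for a
    behaviour, a fraction r of each cell keeps its observed (true) level
    because unknown exposures are never recoded.
    """
    years = years or config.cycle_years
    pafs: dict[tuple[str, str, int], float] = {}
    for year in years:
        cells = _enumerate_cells(config, year)
        p = cells["p"].to_numpy()
        for sector in SECTORS:
            # multiplicative factor per variable level
            factors = {}
            for variable in ["age_group", "education", "deprivation",
                             *BEHAVIOUR_VARIABLES]:
                factors[variable] = np.array([
                    np.exp(_sector_log_ratio(config, sector, variable, l))
                    for l in cells[variable]
                ])
            base = config.baseline_annual_cost[sector]
            mu = base * np.prod(np.vstack(list(factors.values())), axis=0)
            total = float((p * mu).sum())

            def cf_total(rule_vars: list[str]) -> float:
                adj = np.ones(len(cells))
                for v in rule_vars:
                    r = config.missingness.get(v, 0.0)
                    ref_factor = np.exp(
                        _sector_log_ratio(config, sector, v, REFERENCE_LEVELS[v])
                    )
                    adj *= ((1 - r) * ref_factor + r * factors[v]) / factors[v]
                return float((p * mu * adj).sum())

            for b in BEHAVIOUR_VARIABLES:
                pafs[(b, sector, year)] = (total - cf_total([b])) / total
            pafs[("combined", sector, year)] = (
                (total - cf_total(BEHAVIOUR_VARIABLES)) / total
            )
            # SES rule: education and deprivation carry generating effects;
            # income and home ownership have none, so recoding them is a no-op
            pafs[("ses", sector, year)] = (
                (total - cf_total(["education", "deprivation"])) / total
            )
    truth = GroundTruth(paf=pafs, cost_ratios=config.coefficients)
    truth.combined_paf = {
        (sector, year): pafs[("combined", sector, year)]
        for sector in SECTORS for year in years
    }
    return truth


def true_total_paf(config: GeneratorConfig, year: int,
                   risk: str = "combined") -> float:
    """Budget-weighted all-sector PAF of the generating model for a year.

    Sector PAFs are combined with weights equal to each sector's share of
    the enumerated total spend (the 'other' sector carries the community
    PAF, mirroring the attribution convention).
    """
    truth = true_paf(config, years=[year])
    budgets = expected_sector_budgets(config, year)
    num = den = 0.0
    for sector in SECTORS + ["other"]:
        proxy = "community" if sector == "other" else sector
        num += truth.paf[(risk, proxy, year)] * budgets[sector]
        den += budgets[sector]
    return num / den


def expected_sector_budgets(config: GeneratorConfig, year: int
                            ) -> dict[str, float]:
    """Population-scaled expected annual spend per sector (2014 dollars)."""
    cells = _enumerate_cells(config, year)
    p = cells["p"].to_numpy()
    budgets = {}
    for sector in SECTORS:
        factors = np.ones(len(cells))
        for variable in ("age_group", "education", "deprivation",
                         *BEHAVIOUR_VARIABLES):
            factors *= np.array([
                np.exp(_sector_log_ratio(config, sector, variable, l))
                for l in cells[variable]
            ])
        mean = config.baseline_annual_cost[sector] * factors
        budgets[sector] = float((p * mean).sum()) * config.population_size
    s = config.other_share
    budgets["other"] = s / (1.0 - s) * sum(budgets[k] for k in SECTORS)
    return budgets


def generate_expenditure_tables(
    config: GeneratorConfig,
) -> tuple[ExpenditureTable, CpiSeries]:
    """Nominal annual sector budgets and a CPI series (base 2014).

    Budgets follow the cohort's expected per-person costs scaled to the
    configured represented population, with the 'other' sector a fixed
    share of the total; amounts are deflated to nominal dollars with the
    generated CPI so the burden stage must inflate them back.
    """
    years = list(range(config.cycle_years[0], config.cycle_years[-1] + 1))
    cpi = CpiSeries(index={
        y: float((1.0 + config.cpi_annual_inflation) ** (y - BASE_YEAR))
        for y in [*years, BASE_YEAR]
    })
    rows = []
    for year in years:
        budgets = expected_sector_budgets(config, year)
        for sector, amount_2014 in budgets.items():
            nominal = amount_2014 / cpi.ratio(year)
            rows.append((year, sector, nominal))
    table = ExpenditureTable(
        pd.DataFrame(rows, columns=["year", "sector", "amount"]),
        currency_year="nominal",
    )
    return table, cpi
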