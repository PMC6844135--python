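"""Deterministic scoring of raw survey responses into exposure categories.

Behaviour categories follow the standard survey definitions: smoking status
split by current/former and a 20 cigarettes/day threshold; alcohol split by
bingeing and sex-specific weekly-drink thresholds (>21 men, >14 women); diet
summarized by a fruit-and-vegetable index on a 0–10 scale; leisure-time
physical activity summarized as average MET-hours per day with 1.5 and 3
MET·h/day cut-points.  Neighbourhood deprivation combines material and
social quintiles of the area-based deprivation index: the 25 cross-tabulated
quintile cells collapse to low (both quintiles 1–2), high (both 4–5) and
moderate (the remaining 17 cells).

All categorizers are total over non-missing inputs; any missing raw field
required by a rule yields the explicit category ``"missing"``, which is kept
as a modelling level rather than dropping rows.

Boundary conventions: every "X to <Y" range is left-closed/right-open;
">="/"<=" thresholds are inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = "missing"

#: cigarettes/day separating heavy from light (current or former daily smokers)
HEAVY_CIGS_PER_DAY = 20
#: weekly-drink thresholds above which drinking is heavy
DRINK_THRESHOLD = {"male": 21, "female": 14}
#: diet index cut-points: poor < 2.5 <= fair < 5 <= adequate
DIET_CUTS = (2.5, 5.0)
#: MET-hours/day cut-points: inactive < 1.5 <= moderate < 3 <= active
ACTIVITY_CUTS = (1.5, 3.0)
#: potato servings/day above which points are deducted, by sex
POTATO_THRESHOLD = {"male": 1.0, "female": 0.7}

SMOKING_LEVELS = ["non", "light", "heavy", "former_light", "former_heavy", MISSING]
ALCOHOL_LEVELS = ["moderate", "heavy", "non", MISSING]
DIET_LEVELS = ["adequate", "fair", "poor", MISSING]
ACTIVITY_LEVELS = ["active", "moderate", "inactive", MISSING]
DEPRIVATION_LEVELS = ["low", "moderate", "high", MISSING]

AGE_GROUPS = [
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54", "55-59",
    "60-64", "65-69", "70-74", "75-79", "80-84", "85-89", "90+",
]

#: level order (reference level first) for every categorical modelling
#: variable in the cohort schema.  Reference levels for behaviours are the
#: lowest-risk categories; SES references are the lowest-cost categories.
VOCABULARY: dict[str, list[str]] = {
    "age_group": list(AGE_GROUPS),
    "smoking": SMOKING_LEVELS,
    "alcohol": ALCOHOL_LEVELS,
    "diet": DIET_LEVELS,
    "activity": ACTIVITY_LEVELS,
    "education": ["postsecondary", "highschool", "lt_highschool", MISSING],
    "income": ["ge80k", "30to80k", "lt30k", MISSING],
    "home_owned": ["yes", "no", MISSING],
    "deprivation": DEPRIVATION_LEVELS,
    "immigrant": ["no", "yes", MISSING],
    "marital": ["married", "other", MISSING],
    "urban": ["yes", "no", MISSING],
    "ethnicity": ["white", "nonwhite", MISSING],
    "stress": ["low", "high", MISSING],
    "flu_shot": ["no", "yes", MISSING],
    "bmi": ["normal", "underweight", "overweight", "obese", "morbidly_obese", MISSING],
    "hypertension": ["no", "yes", MISSING],
    "diabetes": ["no", "yes", MISSING],
    "heart_disease": ["no", "yes", MISSING],
    "cancer": ["no", "yes", MISSING],
    "stroke": ["no", "yes", MISSING],
    "dementia": ["no", "yes", MISSING],
    "fragility": ["none", "limitation", "needs_help", MISSING],
}

BEHAVIOUR_VARIABLES = ["smoking", "alcohol", "diet", "activity"]
SES_VARIABLES = ["education", "income", "home_owned", "deprivation"]

#: lowest-risk (reference / counterfactual "no exposure") level per variable
REFERENCE_LEVELS: dict[str, str] = {
    "smoking": "non",
    "alcohol": "moderate",
    "diet": "adequate",
    "activity": "active",
    "education": "postsecondary",
    "income": "ge80k",
    "home_owned": "yes",
    "deprivation": "low",
}


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


@dataclass
class RawBehaviourResponse:
    """Raw survey answers needed to score the four behaviours.

    Any field may be None (missing).  ``activities`` holds
    (sessions_per_week, hours_per_session, met_value) triples for
    leisure-time activities; ``cigs_per_day`` is the current daily amount for
    current daily smokers and the former daily amount for former daily
    smokers.
    """

    smoking_status: str | None = None
    cigs_per_day: float | None = None
    lifetime_cigs_ge_100: bool | None = None
    drinks_per_week: float | None = None
    binge_any_day_prev_week: bool | None = None
    weekly_binge_prev_month: bool | None = None
    any_alcohol_12mo: bool | None = None
    activities: Sequence[tuple[float, float, float]] = field(default_factory=list)
    fv_servings: float | None = None
    juice_servings: float | None = None
    carrot_consumed: bool | None = None
    potato_servings: float | None = None


def categorize_smoking(
    smoking_status,
    cigs_per_day=None,
    lifetime_cigs_ge_100=None,
) -> str:
    """Collapse smoking status + amounts into the five-level category.

    Heavy/light splits at >=20 cigarettes/day for current and former daily
    smokers; occasional smokers are light (former light) when they have
    smoked at least 100 lifetime cigarettes, otherwise non-smokers.
    """
    if _is_missing(smoking_status):
        return MISSING
    if cigs_per_day is not None and not _is_missing(cigs_per_day) and cigs_per_day < 0:
        raise ValueError(f"cigs_per_day must be non-negative, got {cigs_per_day}")
    status = str(smoking_status)
    if status == "never":
        return "non"
    if status in ("current_daily", "former_daily"):
        if _is_missing(cigs_per_day):
            return MISSING
        heavy = cigs_per_day >= HEAVY_CIGS_PER_DAY
        if status == "current_daily":
            return "heavy" if heavy else "light"
        return "former_heavy" if heavy else "former_light"
    if status in ("current_occasional", "former_occasional"):
        if _is_missing(lifetime_cigs_ge_100):
            return MISSING
        if not lifetime_cigs_ge_100:
            return "non"
        return "light" if status == "current_occasional" else "former_light"
    raise ValueError(f"unknown smoking_status {smoking_status!r}")


def categorize_alcohol(
    sex,
    drinks_per_week=None,
    binge_any_day_prev_week=None,
    weekly_binge_prev_month=None,
    any_alcohol_12mo=None,
) -> str:
    """Heavy / moderate / non drinking category.

    Heavy: bingeing (either binge indicator true) or weekly drinks above the
    sex-specific threshold.  Moderate: at-or-below threshold, no bingeing,
    and any alcohol in the last 12 months.  Non: no alcohol in 12 months.
    When the binge indicators conflict with missingness, either true means
    bingeing.
    """
    if sex not in DRINK_THRESHOLD:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if not _is_missing(drinks_per_week) and drinks_per_week < 0:
        raise ValueError(f"drinks_per_week must be non-negative, got {drinks_per_week}")
    if any_alcohol_12mo is False:
        return "non"
    binge = (binge_any_day_prev_week is True) or (weekly_binge_prev_month is True)
    if binge:
        return "heavy"
    if _is_missing(drinks_per_week):
        return MISSING
    if drinks_per_week > DRINK_THRESHOLD[sex]:
        return "heavy"
    # at or below the threshold with no bingeing: moderate requires knowing
    # the person drank at all in the last year
    if any_alcohol_12mo is True or drinks_per_week > 0:
        return "moderate"
    return MISSING


def compute_met_hours(activities: Iterable[tuple[float, float, float]]) -> float:
    """Average daily leisure-time energy expenditure in MET-hours/day.

    Each activity contributes (sessions_per_week / 7) x hours_per_session x
    MET value, using the low-intensity MET value of the activity.
    """
    total = 0.0
    for sessions_per_week, hours_per_session, met_value in activities:
        if sessions_per_week < 0 or hours_per_session < 0:
            raise ValueError("sessions_per_week and hours_per_session must be >= 0")
        if met_value <= 0:
            raise ValueError("met_value must be positive")
        total += (sessions_per_week / 7.0) * hours_per_session * met_value
    return total


def categorize_activity(met_hours_per_day) -> str:
    """inactive < 1.5 <= moderate < 3 <= active, in MET-hours/day."""
    if _is_missing(met_hours_per_day):
        return MISSING
    if met_hours_per_day < 0:
        raise ValueError("met_hours_per_day must be >= 0")
    lo, hi = ACTIVITY_CUTS
    if met_hours_per_day < lo:
        return "inactive"
    if met_hours_per_day < hi:
        return "moderate"
    return "active"


def diet_score(
    fv_servings,
    juice_servings,
    carrot_consumed,
    potato_servings,
    sex,
) -> float:
    """Fruit-and-vegetable diet index on a 0-10 scale.

    Start at 2 points; add one point per average daily fruit/vegetable
    serving up to 8 additional points; deduct 2 points each for fruit-juice
    servings exceeding 1/day, for no carrot consumption, and for potato
    servings exceeding 1/day (men) or 0.7/day (women).  Negative totals are
    recoded to 0.  Fractional servings accrue fractional points before the
    cap.  Returns NaN if any required field is missing.
    """
    if sex not in POTATO_THRESHOLD:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if any(
        _is_missing(v)
        for v in (fv_servings, juice_servings, carrot_consumed, potato_servings)
    ):
        return float("nan")
    if fv_servings < 0 or juice_servings < 0 or potato_servings < 0:
        raise ValueError("servings must be non-negative")
    score = 2.0 + min(8.0, float(fv_servings))
    if juice_servings > 1:
        score -= 2.0
    if not carrot_consumed:
        score -= 2.0
    if potato_servings > POTATO_THRESHOLD[sex]:
        score -= 2.0
    return max(0.0, score)


def categorize_diet(score) -> str:
    """poor < 2.5 <= fair < 5 <= adequate, on the 0-10 index."""
    if _is_missing(score):
        return MISSING
    if not 0 <= score <= 10:
        raise ValueError(f"diet score must be in [0, 10], got {score}")
    lo, hi = DIET_CUTS
    if score < lo:
        return "poor"
    if score < hi:
        return "fair"
    return "adequate"


def categorize_deprivation(material_q, social_q) -> str:
    """Collapse the 25 material x social quintile cells to low/moderate/high.

    Low: both quintiles in {1,2} (4 cells).  High: both in {4,5} (4 cells).
    Moderate: the remaining 17 cells.  Q1 is least deprived.
    """
    if _is_missing(material_q) or _is_missing(social_q):
        return MISSING
    material_q, social_q = int(material_q), int(social_q)
    for q in (material_q, social_q):
        if not 1 <= q <= 5:
            raise ValueError(f"quintile must be in 1..5, got {q}")
    if material_q <= 2 and social_q <= 2:
        return "low"
    if material_q >= 4 and social_q >= 4:
        return "high"
    return "moderate"


# --- vectorized cohort scoring ------------------------------------------

#: raw input columns consumed by score_cohort (single flattened activity)
RAW_COLUMNS = [
    "smoking_status", "cigs_per_day", "lifetime_cigs_ge_100",
    "drinks_per_week", "binge_any_day_prev_week", "weekly_binge_prev_month",
    "any_alcohol_12mo",
    "activity_sessions_per_week", "activity_hours_per_session",
    "activity_met_value",
    "fv_servings", "juice_servings", "carrot_consumed", "potato_servings",
    "material_quintile", "social_quintile",
]

#: columns appended by score_cohort
SCORED_COLUMNS = [
    "smoking", "alcohol", "diet_score", "diet",
    "met_hours_per_day", "activity", "deprivation",
]


def _opt_bool(value):
    return None if _is_missing(value) else bool(value)


def score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append categorized exposure columns to a raw cohort table.

    Expects the raw response columns in :data:`RAW_COLUMNS` (leisure
    activity flattened to a single sessions/hours/MET triple) plus ``sex``;
    returns a copy with :data:`SCORED_COLUMNS` appended.  Missing raw fields
    propagate to the explicit ``"missing"`` category.
    """
    out = cohort.copy()
    n = len(out)

    smoking = np.empty(n, dtype=object)
    alcohol = np.empty(n, dtype=object)
    dscore = np.empty(n, dtype=float)
    met = np.empty(n, dtype=float)
    depriv = np.empty(n, dtype=object)

    sex = out["sex"].to_numpy()
    cols = {c: out[c].to_numpy() for c in RAW_COLUMNS if c in out.columns}

    def get(c, i):
        arr = cols.get(c)
        return None if arr is None else arr[i]

    for i in range(n):
        smoking[i] = categorize_smoking(
            get("smoking_status", i), get("cigs_per_day", i),
            _opt_bool(get("lifetime_cigs_ge_100", i)),
        )
        alcohol[i] = categorize_alcohol(
            sex[i], get("drinks_per_week", i),
            _opt_bool(get("binge_any_day_prev_week", i)),
            _opt_bool(get("weekly_binge_prev_month", i)),
            _opt_bool(get("any_alcohol_12mo", i)),
        )
        dscore[i] = diet_score(
            get("fv_servings", i), get("juice_servings", i),
            _opt_bool(get("carrot_consumed", i)), get("potato_servings", i),
            sex[i],
        )
        spw, hps, mv = (
            get("activity_sessions_per_week", i),
            get("activity_hours_per_session", i),
            get("activity_met_value", i),
        )
        if _is_missing(spw) or _is_missing(hps) or _is_missing(mv):
            met[i] = float("nan")
        else:
            met[i] = compute_met_hours([(spw, hps, mv)])
        depriv[i] = categorize_deprivation(
            get("material_quintile", i), get("social_quintile", i)
        )

    out["smoking"] = smoking
    out["alcohol"] = alcohol
    out["diet_score"] = dscore
    out["diet"] = [categorize_diet(s) if not math.isnan(s) else MISSING for s in dscore]
    out["met_hours_per_day"] = met
    out["activity"] = [
        categorize_activity(m) if not math.isnan(m) else MISSING for m in met
    ]
    out["deprivation"] = depriv
    return out
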