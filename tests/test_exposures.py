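"""Exposure categorizer unit and property tests.

Each cut-point is exercised at, just below, and just above the threshold;
the diet index is checked exactly against an independent brute-force oracle
over a servings grid; the deprivation mapping is enumerated over all 25
quintile cells.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from costpaf import exposures, synthetic
from costpaf.exposures import (
    categorize_activity,
    categorize_alcohol,
    categorize_deprivation,
    categorize_diet,
    categorize_smoking,
    compute_met_hours,
    diet_score,
)


@pytest.mark.parametrize(
    "status, cigs, lifetime, expected",
    [
        ("current_daily", 25, None, "heavy"),
        ("current_daily", 20, None, "heavy"),       # inclusive boundary
        ("current_daily", 19.9, None, "light"),
        ("current_daily", 1, None, "light"),
        ("current_occasional", None, True, "light"),
        ("current_occasional", None, False, "non"),
        ("former_daily", 20, None, "former_heavy"),
        ("former_daily", 21, None, "former_heavy"),
        ("former_daily", 19, None, "former_light"),
        ("former_occasional", None, True, "former_light"),
        ("former_occasional", None, False, "non"),
        ("never", None, False, "non"),
        ("never", None, None, "non"),
        (None, None, None, "missing"),
        ("current_daily", None, None, "missing"),
        ("current_occasional", None, None, "missing"),
    ],
)
def test_smoking_categories(status, cigs, lifetime, expected):
    assert categorize_smoking(status, cigs, lifetime) == expected


def test_smoking_negative_amount_rejected():
    with pytest.raises(ValueError):
        categorize_smoking("current_daily", -1)


@pytest.mark.parametrize(
    "sex, drinks, binge_week, binge_month, any12, expected",
    [
        ("male", 10, True, False, True, "heavy"),     # bingeing dominates
        ("male", 10, False, True, True, "heavy"),
        ("male", 22, False, False, True, "heavy"),    # just above threshold
        ("male", 21, False, False, True, "moderate"), # inclusive <=21
        ("female", 15, False, False, True, "heavy"),
        ("female", 14, False, False, True, "moderate"),
        ("female", 13.9, False, False, True, "moderate"),
        ("male", 5, False, False, False, "non"),      # non overrides drinks
        ("female", 0, False, False, False, "non"),
        ("male", None, None, None, None, "missing"),
        ("male", None, True, None, None, "heavy"),    # either binge flag
        ("male", 3, False, False, None, "moderate"),  # drinking implies alcohol
        ("male", 0, False, False, None, "missing"),
    ],
)
def test_alcohol_categories(sex, drinks, binge_week, binge_month, any12, expected):
    assert (
        categorize_alcohol(sex, drinks, binge_week, binge_month, any12)
        == expected
    )


def test_alcohol_requires_known_sex():
    with pytest.raises(ValueError):
        categorize_alcohol("other", 5)


@pytest.mark.parametrize(
    "activities, expected",
    [
        ([], 0.0),
        ([(7, 1, 3.0)], 3.0),
        ([(3.5, 2, 3.0)], 3.0),
        ([(7, 0.5, 2.0), (7, 0.5, 4.0)], 3.0),
    ],
)
def test_met_hours(activities, expected):
    assert compute_met_hours(activities) == pytest.approx(expected)


def test_met_hours_negative_duration_rejected():
    with pytest.raises(ValueError):
        compute_met_hours([(7, -1, 3.0)])


@pytest.mark.parametrize(
    "met, expected",
    [
        (0.0, "inactive"),
        (1.4999, "inactive"),
        (1.5, "moderate"),      # left-closed boundary
        (2.9999, "moderate"),
        (3.0, "active"),
        (10.0, "active"),
    ],
)
def test_activity_categories(met, expected):
    assert categorize_activity(met) == expected


@pytest.mark.parametrize(
    "score, expected",
    [
        (0.0, "poor"),
        (2.4999, "poor"),
        (2.5, "fair"),
        (4.9999, "fair"),
        (5.0, "adequate"),
        (10.0, "adequate"),
    ],
)
def test_diet_categories(score, expected):
    assert categorize_diet(score) == expected


def oracle_diet_score(fv, juice, carrot, potato, sex):
    """Independent re-derivation of the index arithmetic: start with 2,
    one point per daily fruit/vegetable serving capped at 8 extra, three
    2-point deductions, floor at zero."""
    pts = 2.0
    pts += fv if fv < 8 else 8.0
    deductions = 0.0
    if juice > 1:
        deductions += 2
    if not carrot:
        deductions += 2
    limit = {"male": 1.0, "female": 0.7}[sex]
    if potato > limit:
        deductions += 2
    total = pts - deductions
    return total if total > 0 else 0.0


def test_diet_score_matches_bruteforce_oracle_on_grid():
    fvs = np.arange(0, 12.5, 0.5)
    juices = [0, 0.5, 1, 1.5]
    carrots = [False, True]
    potatoes = [0, 0.5, 0.7, 0.71, 1, 1.01]
    for fv, j, c, p, sex in itertools.product(
        fvs, juices, carrots, potatoes, ["male", "female"]
    ):
        assert diet_score(fv, j, c, p, sex) == oracle_diet_score(fv, j, c, p, sex)


@pytest.mark.parametrize(
    "args, expected",
    [
        ((9, 0.5, True, 0.3, "female"), 10.0),   # saturating healthy profile
        ((0, 2, False, 1.5, "male"), 0.0),       # deduction floor
        ((3, 0, True, 0, "male"), 5.0),
        ((8, 1, True, 1, "male"), 10.0),         # juice/potato at inclusive limits
        ((8, 1.0001, True, 0.7001, "female"), 6.0),
    ],
)
def test_diet_score_worked_examples(args, expected):
    assert diet_score(*args) == expected


@given(
    fv=st.floats(0, 50, allow_nan=False),
    juice=st.floats(0, 10, allow_nan=False),
    carrot=st.booleans(),
    potato=st.floats(0, 10, allow_nan=False),
    sex=st.sampled_from(["male", "female"]),
)
def test_diet_score_always_in_range(fv, juice, carrot, potato, sex):
    s = diet_score(fv, juice, carrot, potato, sex)
    assert 0.0 <= s <= 10.0


def test_diet_score_missing_field_gives_nan():
    assert math.isnan(diet_score(None, 0, True, 0, "male"))
    assert math.isnan(diet_score(3, None, True, 0, "male"))


def test_deprivation_enumerates_25_cells_4_low_4_high():
    cats = {
        (m, s): categorize_deprivation(m, s)
        for m in range(1, 6)
        for s in range(1, 6)
    }
    counts = pd.Series(cats).value_counts()
    assert len(cats) == 25
    assert counts["low"] == 4
    assert counts["high"] == 4
    assert counts["moderate"] == 17
    assert cats[(1, 2)] == "low"
    assert cats[(5, 4)] == "high"
    assert cats[(1, 5)] == "moderate"


def test_deprivation_rejects_out_of_range_quintile():
    with pytest.raises(ValueError):
        categorize_deprivation(0, 3)
    with pytest.raises(ValueError):
        categorize_deprivation(2, 6)


def test_score_cohort_agrees_with_scalar_categorizers(small_cohort):
    """Vectorized cohort scoring and the scalar rules are one code path in
    effect: spot-check agreement on generated rows."""
    sample = small_cohort.sample(200, random_state=0)
    for _, row in sample.iterrows():
        assert row["smoking"] == categorize_smoking(
            row["smoking_status"],
            row["cigs_per_day"],
            None if pd.isna(row["lifetime_cigs_ge_100"])
            else bool(row["lifetime_cigs_ge_100"]),
        )
        assert row["deprivation"] == categorize_deprivation(
            row["material_quintile"], row["social_quintile"]
        )
        if not math.isnan(row["met_hours_per_day"]):
            assert row["activity"] == categorize_activity(row["met_hours_per_day"])
        if not math.isnan(row["diet_score"]):
            assert row["diet"] == categorize_diet(row["diet_score"])


def test_score_cohort_missing_raw_fields_yield_missing_category():
    cfg = synthetic.GeneratorConfig(
        n_per_cycle=500, cycle_years=[2003], linked_cycle_years=[2003],
        missingness={"smoking": 0.2, "alcohol": 0.2, "diet": 0.2,
                     "activity": 0.2},
    )
    coh = synthetic.generate_cohort(cfg, seed=3)
    for b in ["smoking", "alcohol", "diet", "activity"]:
        assert (coh[b] == "missing").mean() > 0.1
        # non-missing rows still recover the sampled category
        ok = coh[b] != "missing"
        assert (coh.loc[ok, b] == coh.loc[ok, f"true_{b}"]).all()
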