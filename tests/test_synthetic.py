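"""Generator tests: determinism, round-trip, truth enumeration, budgets."""

import numpy as np
import pandas as pd
import pytest

from costpaf import attribution, cost_models, synthetic
from costpaf.synthetic import (
    GeneratorConfig,
    behaviour_prevalence_at,
    expected_sector_budgets,
    generate_cohort,
    generate_expenditure_tables,
    true_paf,
)


def null_effect_config(**kw):
    """All cost ratios 1: every coefficient and the age gradient zeroed."""
    zero = {s: {} for s in synthetic.SECTORS}
    return GeneratorConfig(
        coefficients=zero,
        age_gradient={s: 0.0 for s in synthetic.SECTORS},
        **kw,
    )


def test_generation_is_deterministic_given_seed():
    cfg = GeneratorConfig(n_per_cycle=400, cycle_years=[2003, 2005],
                          linked_cycle_years=[2003])
    a = generate_cohort(cfg, seed=5)
    b = generate_cohort(cfg, seed=5)
    assert a.to_csv(index=False) == b.to_csv(index=False)
    c = generate_cohort(cfg, seed=6)
    assert a.to_csv(index=False) != c.to_csv(index=False)


def test_roundtrip_scoring_recovers_sampled_categories(small_cohort):
    for b in ["smoking", "alcohol", "diet", "activity"]:
        non_missing = small_cohort[b] != "missing"
        agree = (small_cohort.loc[non_missing, b]
                 == small_cohort.loc[non_missing, f"true_{b}"])
        assert agree.all()
        # missingness only where injected
        rate = (~non_missing).mean()
        assert rate < 0.08
    dep_ok = small_cohort["deprivation"] == small_cohort["true_deprivation"]
    assert dep_ok.all()


def test_zero_effect_config_mean_cost_matches_baseline():
    cfg = null_effect_config(n_per_cycle=20_000, cycle_years=[2003],
                             linked_cycle_years=[2003])
    coh = generate_cohort(cfg, seed=12)
    for sector in synthetic.SECTORS:
        annualized = coh[f"cost_{sector}"] / coh["person_years"]
        baseline = cfg.baseline_annual_cost[sector]
        # NB mean-variance: var = mu^2 alpha / py approx; 2 SE band
        se = annualized.std() / np.sqrt(len(coh))
        assert abs(annualized.mean() - baseline) < 2 * se + 1.0


def test_invalid_prevalence_vector_rejected():
    with pytest.raises(ValueError, match="sum"):
        GeneratorConfig(behaviour_prevalence={
            "smoking": {"heavy": (0.5, 0.5), "non": (0.4, 0.5)},
            "alcohol": {"moderate": (1.0, 1.0)},
            "diet": {"adequate": (1.0, 1.0)},
            "activity": {"active": (1.0, 1.0)},
        })
    with pytest.raises(ValueError):
        GeneratorConfig(followup_probs={1: 0.5, 5: 0.5})


def test_confounding_tilts_risky_levels_towards_disadvantage():
    cfg = GeneratorConfig(confounding_strength=0.5)
    p_dis = behaviour_prevalence_at(cfg, "smoking", 2003, "lt_highschool")
    p_adv = behaviour_prevalence_at(cfg, "smoking", 2003, "postsecondary")
    assert p_dis["heavy"] > p_adv["heavy"]
    assert p_dis["non"] < p_adv["non"]
    flat = behaviour_prevalence_at(
        GeneratorConfig(confounding_strength=0.0), "smoking", 2003,
        "lt_highschool",
    )
    base = {l: p[0] for l, p in cfg.behaviour_prevalence["smoking"].items()}
    assert flat == pytest.approx(base)


def test_prevalence_drift_interpolates_linearly():
    cfg = GeneratorConfig(confounding_strength=0.0)
    p0 = behaviour_prevalence_at(cfg, "smoking", 2003, "highschool")["heavy"]
    p1 = behaviour_prevalence_at(cfg, "smoking", 2013, "highschool")["heavy"]
    mid = behaviour_prevalence_at(cfg, "smoking", 2008, "highschool")["heavy"]
    assert mid == pytest.approx((p0 + p1) / 2)


def test_true_paf_closed_form_binary_exposure():
    """Single binary exposure, homogeneous baseline, p=0.5, rho=2 -> 1/3."""
    cfg = null_effect_config(
        behaviour_prevalence={
            "smoking": {"heavy": (0.5, 0.5), "non": (0.5, 0.5)},
            "alcohol": {"moderate": (1.0, 1.0)},
            "diet": {"adequate": (1.0, 1.0)},
            "activity": {"active": (1.0, 1.0)},
        },
        confounding_strength=0.0,
        missingness={},
        cycle_years=[2003], linked_cycle_years=[2003],
    )
    cfg.coefficients["hospital"]["smoking"] = {"heavy": float(np.log(2.0))}
    truth = true_paf(cfg)
    assert truth.paf[("smoking", "hospital", 2003)] == pytest.approx(
        1.0 / 3.0, abs=1e-12
    )
    # untouched sectors have no effect, hence zero PAF
    assert truth.paf[("smoking", "drugs", 2003)] == pytest.approx(0.0)


def test_true_paf_zero_when_all_ratios_one():
    cfg = null_effect_config(cycle_years=[2003], linked_cycle_years=[2003])
    truth = true_paf(cfg)
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in truth.paf.values())


def test_true_paf_agrees_with_monte_carlo():
    """Enumeration vs a direct simulation of the generating mechanism."""
    cfg = GeneratorConfig(n_per_cycle=50_000, cycle_years=[2003],
                          linked_cycle_years=[2003])
    coh = generate_cohort(cfg, seed=13)
    # Monte Carlo: generating-model means from the sampled true categories,
    # counterfactual recodes non-missing observed categories to reference
    sector = "hospital"
    def gen_mu(frame, smoking_col):
        eta = np.log(cfg.baseline_annual_cost[sector]) + \
            cfg.age_gradient[sector] * frame["age_group"].map(
                synthetic.AGE_GROUPS.index)
        for var in ("alcohol", "diet", "activity"):
            coefs = cfg.coefficients[sector].get(var, {})
            eta = eta + frame[f"true_{var}"].map(
                lambda l: coefs.get(l, 0.0))
        for var in ("education",):
            coefs = cfg.coefficients[sector].get(var, {})
            eta = eta + frame[var].map(lambda l: coefs.get(l, 0.0))
        coefs = cfg.coefficients[sector].get("deprivation", {})
        eta = eta + frame["true_deprivation"].map(lambda l: coefs.get(l, 0.0))
        smoke_coefs = cfg.coefficients[sector].get("smoking", {})
        eta = eta + frame[smoking_col].map(lambda l: smoke_coefs.get(l, 0.0))
        return np.exp(eta)

    mu = gen_mu(coh, "true_smoking")
    cf = coh.copy()
    cf["cf_smoking"] = np.where(
        cf["smoking"] == "missing", cf["true_smoking"], "non"
    )
    mu0 = gen_mu(cf, "cf_smoking")
    mc = (mu.sum() - mu0.sum()) / mu.sum()
    truth = true_paf(cfg, years=[2003]).paf[("smoking", "hospital", 2003)]
    assert mc == pytest.approx(truth, abs=0.01)


def test_budgets_scale_with_population_and_other_share_exact():
    cfg = GeneratorConfig(cycle_years=[2003], linked_cycle_years=[2003])
    b1 = expected_sector_budgets(cfg, 2003)
    cfg2 = cfg.model_copy(update={"population_size": 2 * cfg.population_size})
    b2 = expected_sector_budgets(cfg2, 2003)
    for sector, v in b1.items():
        assert b2[sector] == pytest.approx(2 * v)
    total = sum(b1.values())
    assert b1["other"] / total == pytest.approx(cfg.other_share)


def test_expenditure_tables_structure_and_cpi():
    cfg = GeneratorConfig(n_per_cycle=100, cycle_years=[2003],
                          linked_cycle_years=[2003])
    table, cpi = generate_expenditure_tables(cfg)
    assert table.years == [2003]
    assert len(table.data) == 4
    assert table.currency_year == "nominal"
    idx = cpi.to_frame().set_index("year")["cpi"]
    assert (idx.diff().dropna() > 0).all()     # monotone
    assert idx[2014] == pytest.approx(1.0)


def test_informative_weights_shift_paf_towards_weighted_truth():
    """Upweighting smokers emulates a population with more smoking than the
    sample; the weighted PAF moves toward that population's truth."""
    cfg = GeneratorConfig(
        n_per_cycle=20_000, cycle_years=[2003], linked_cycle_years=[2003],
        confounding_strength=0.0, missingness={},
    )
    coh = generate_cohort(cfg, seed=14)
    factor = 3.0
    smoker = coh["smoking"].isin(["heavy", "light"])
    coh = coh.copy()
    coh["weight"] = np.where(smoker, factor, 1.0)
    models = {
        sex: cost_models.fit_cost_model(coh, sex, "hospital", 1)
        for sex in ("male", "female")
    }
    rule = attribution.behaviour_rule("smoking")
    weighted = attribution.paf(models, coh, rule)
    unweighted = attribution.paf(
        models, coh.assign(weight=1.0), rule
    )
    # population truth: prevalences tilted by the weighting factor
    base = {l: p[0] for l, p in cfg.behaviour_prevalence["smoking"].items()}
    tilt = {l: (factor if l in ("heavy", "light") else 1.0) * p
            for l, p in base.items()}
    z = sum(tilt.values())
    tilted = {l: v / z for l, v in tilt.items()}
    cfg_pop = cfg.model_copy(update={"behaviour_prevalence": {
        **cfg.behaviour_prevalence,
        "smoking": {l: (p, p) for l, p in tilted.items()},
    }})
    truth_pop = true_paf(cfg_pop, years=[2003]).paf[("smoking", "hospital", 2003)]
    assert abs(weighted - truth_pop) < abs(unweighted - truth_pop)


def test_full_pipeline_decade_recovery():
    """Decade run with drifting smoking prevalence: exposures -> step-3 NB
    models -> PAFs -> burden recovers the generating truth — combined
    hospital PAF per cycle year within 0.015, and smoking's share of
    avoided costs within 10 percentage points of the generator's truth."""
    from costpaf import burden, cohort_io, pipeline

    cfg = GeneratorConfig()
    coh = generate_cohort(cfg, seed=7)
    linked = coh[coh["cycle_year"].isin(cfg.linked_cycle_years)]
    suite = cost_models.fit_model_suite(linked, steps=[3])
    run_cfg = cohort_io.RunConfig(cohort_path="<in-memory>")
    cycle_pafs = pipeline.compute_cycle_pafs(suite, coh, run_cfg)

    truth = true_paf(cfg)
    for year in cfg.cycle_years:
        est = cycle_pafs[("combined", "hospital")][year]
        assert abs(est - truth.paf[("combined", "hospital", year)]) < 0.015

    years = list(range(cfg.cycle_years[0], cfg.cycle_years[-1] + 1))
    paf_table = attribution.paf_series_table(cycle_pafs, years)
    expn, cpi = generate_expenditure_tables(cfg)
    expend = expn.to_2014(cpi)
    budgets = {y: expend.total(y) for y in years if y > 2003}

    def avoided_total(annual, baseline):
        return burden.avoided_costs(baseline, annual, budgets)["avoided"].sum()

    est_av, tru_av = {}, {}
    for risk in ["smoking", "alcohol", "diet", "activity"]:
        base_est = pipeline.total_budget_paf(paf_table, expend, risk, 2003)
        annual_est = {
            y: pipeline.total_budget_paf(paf_table, expend, risk, y)
            for y in budgets
        }
        est_av[risk] = avoided_total(annual_est, base_est)
        tru_cycle = {
            y: synthetic.true_total_paf(cfg, y, risk) for y in cfg.cycle_years
        }
        tru_series = attribution.annual_paf_series(tru_cycle, years)
        tmap = dict(zip(tru_series["year"], tru_series["paf"]))
        tru_av[risk] = avoided_total({y: tmap[y] for y in budgets}, tmap[2003])

    share_est = 100 * est_av["smoking"] / sum(est_av.values())
    share_tru = 100 * tru_av["smoking"] / sum(tru_av.values())
    assert abs(share_est - share_tru) < 10
    # declining smoking drives avoided costs beyond its attributable share
    assert est_av["smoking"] > 0
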