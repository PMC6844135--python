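"""End-to-end orchestration: score, fit, attribute, account, stress-test.

``run_pipeline`` executes the full analysis on a linked fitting cohort and
unlinked prediction cycles: exposure scoring, the NB cost-model ladder,
per-cycle factor-deleted PAFs with between-cycle interpolation, expenditure
attribution with CPI inflation, avoided-cost counterfactuals, and the
optional sensitivity analyses, writing tidy CSV outputs plus a
machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

import costpaf
from costpaf import attribution, burden, cohort_io, cost_models, exposures, sensitivity
from costpaf.cohort_io import RunConfig

logger = logging.getLogger(__name__)

RISK_RULES = {
    "smoking": lambda cfg: attribution.behaviour_rule("smoking"),
    "alcohol": lambda cfg: (
        attribution.RecodingRule({"alcohol": "moderate"}, {"alcohol": ("heavy",)})
        if cfg.alcohol_heavy_only else attribution.behaviour_rule("alcohol")
    ),
    "diet": lambda cfg: attribution.behaviour_rule("diet"),
    "activity": lambda cfg: attribution.behaviour_rule("activity"),
    "combined": lambda cfg: attribution.combined_behaviour_rule(
        alcohol_heavy_only=cfg.alcohol_heavy_only
    ),
    "ses": lambda cfg: attribution.ses_rule(),
}


def _ensure_scored(df: pd.DataFrame) -> pd.DataFrame:
    if all(c in df.columns for c in exposures.SCORED_COLUMNS):
        return df
    return exposures.score_cohort(df)


def compute_cycle_pafs(
    suite: cost_models.ModelSuite,
    unlinked: pd.DataFrame,
    config: RunConfig,
    *,
    step: int = cost_models.PRIMARY_STEP,
) -> dict[tuple[str, str], dict[int, float]]:
    """PAF per (risk, sector) and cycle year on the unlinked cohort."""
    out: dict[tuple[str, str], dict[int, float]] = {}
    for risk in config.risks:
        rule = RISK_RULES[risk](config)
        for sector in cost_models.SECTORS:
            series = {}
            for year, cycle in unlinked.groupby("cycle_year"):
                models = suite.by_sex(sector, step)
                series[int(year)] = attribution.paf(models, cycle, rule)
            out[(risk, sector)] = series
    return out


def total_budget_paf(
    paf_table: pd.DataFrame, expenditures: burden.ExpenditureTable, risk: str,
    year: int,
) -> float:
    """Budget-weighted all-sector PAF for one risk and year."""
    num = den = 0.0
    for sector in burden.SECTORS_WITH_OTHER:
        proxy = (burden.OTHER_PAF_PROXY if sector == burden.OTHER_SECTOR
                 else sector)
        m = (
            (paf_table["risk"] == risk)
            & (paf_table["sector"] == proxy)
            & (paf_table["year"] == year)
        )
        if not m.any():
            raise KeyError(f"no PAF for risk={risk}, sector={proxy}, year={year}")
        p = float(paf_table.loc[m, "paf"].iloc[0])
        amount = expenditures.amount(sector, year)
        num += p * amount
        den += amount
    return num / den


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the result bundle.

    Stages: read/score -> fit ladder (linked role) -> per-cycle PAFs
    (unlinked role) -> interpolate -> attribute expenditure + avoided costs
    (skipped with a notice when no expenditure table is configured) ->
    sensitivity analyses -> manifest.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("score")
        linked = _ensure_scored(cohort_io.read_cohort(config.cohort_path,
                                                      role="linked"))
        unlinked_path = config.unlinked_path or config.cohort_path
        unlinked = _ensure_scored(cohort_io.read_cohort(unlinked_path,
                                                        role="unlinked"))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'score' failed: {exc}") from exc

    try:
        stage("fit")
        suite = cost_models.fit_model_suite(
            linked, steps=config.steps, weighted=config.weighted_fit
        )
        suite.to_json(outdir / "models.json")
        bundle["suite"] = suite
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    try:
        stage("paf")
        cycle_pafs = compute_cycle_pafs(suite, unlinked, config)
        cycle_years = sorted(unlinked["cycle_year"].unique())
        years = list(range(int(cycle_years[0]), int(cycle_years[-1]) + 1))
        paf_table = attribution.paf_series_table(cycle_pafs, years)
        paf_table.to_csv(outdir / "paf.csv", index=False)
        bundle["paf"] = paf_table
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'paf' failed: {exc}") from exc

    if config.expenditure_path and config.cpi_path:
        try:
            stage("burden")
            cpi = cohort_io.read_cpi(config.cpi_path)
            expend = cohort_io.read_expenditure(config.expenditure_path
                                                ).to_2014(cpi)
            att = burden.attribute_expenditure(paf_table, expend)
            baseline_year = config.baseline_year or years[0]
            budgets = {y: expend.total(y) for y in expend.years
                       if y > baseline_year}
            avoided_frames = []
            for risk in config.risks:
                baseline = total_budget_paf(paf_table, expend, risk,
                                            baseline_year)
                annual = {
                    y: total_budget_paf(paf_table, expend, risk, y)
                    for y in budgets
                }
                av = burden.avoided_costs(baseline, annual, budgets)
                av.insert(0, "risk", risk)
                avoided_frames.append(av)
            avoided = pd.concat(avoided_frames, ignore_index=True)
            result = burden.BurdenResult(attributable=att, avoided=avoided)
            result.shares = burden.summarize_burden(
                result,
                risks=[r for r in config.risks
                       if r in exposures.BEHAVIOUR_VARIABLES],
            )
            att.to_csv(outdir / "attributable.csv", index=False)
            avoided.to_csv(outdir / "avoided.csv", index=False)
            result.shares.to_csv(outdir / "shares.csv", index=False)
            bundle["burden"] = result
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'burden' failed: {exc}") from exc
    else:
        logger.info("no expenditure/CPI table configured; burden stage skipped")

    opts = config.sensitivity
    if opts.bounds or opts.trim_top or opts.ipw:
        try:
            stage("sensitivity")
            sens: dict = {}
            if opts.bounds:
                rows = []
                rule = RISK_RULES["combined"](config)
                for sector in cost_models.SECTORS:
                    for year, cycle in unlinked.groupby("cycle_year"):
                        b = sensitivity.bound_estimates(suite, cycle, rule, sector)
                        rows.append((sector, int(year), b.primary, b.upper,
                                     b.lower, b.ordered))
                sens["bounds"] = pd.DataFrame(
                    rows, columns=["sector", "year", "primary", "upper",
                                   "lower", "ordered"],
                )
                sens["bounds"].to_csv(outdir / "sensitivity_bounds.csv",
                                      index=False)
            if opts.trim_top:
                trimmed, report = sensitivity.exclude_top_users(
                    linked, opts.trim_fraction
                )
                std = sensitivity.standard_population(linked)
                rows = []
                for level in exposures.VOCABULARY["smoking"][1:-1]:
                    for label, frame in (("full", linked), ("trimmed", trimmed)):
                        rows.append((level, label,
                                     sensitivity.age_standardized_cost_ratio(
                                         frame, "smoking", level, "non", std)))
                sens["trim"] = pd.DataFrame(
                    rows, columns=["level", "cohort", "cost_ratio"]
                )
                sens["trim_report"] = {k: v for k, v in report.items()
                                       if k != "removed_ids"}
                sens["trim"].to_csv(outdir / "sensitivity_trim.csv", index=False)
            if opts.ipw:
                covariates = [
                    v for v in cost_models.ladder_covariates(
                        cost_models.PRIMARY_STEP)
                    if v != opts.ipw_treatment
                ] + [c for c in sensitivity.IPW_EXTRA_COVARIATES
                     if c in linked.columns]
                ratios = sensitivity.ipw_cost_ratio(
                    linked, opts.ipw_treatment, covariates
                )
                ratios.rename_axis("level").reset_index().to_csv(
                    outdir / "sensitivity_ipw.csv", index=False
                )
                sens["ipw"] = ratios
            bundle["sensitivity"] = sens
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'sensitivity' failed: {exc}"
            ) from exc

    manifest = {
        "seed": config.seed,
        "config": config.model_dump(),
        "config_sha256": cohort_io.config_hash(config),
        "versions": {
            "costpaf": costpaf.__version__,
            "numpy": __import__("numpy").__version__,
            "pandas": pd.__version__,
            "statsmodels": __import__("statsmodels").__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    bundle["manifest"] = manifest
    return bundle
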