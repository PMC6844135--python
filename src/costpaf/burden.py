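"""Attributable and avoided dollars from PAF series and expenditures.

Annual attributable costs are PAF x expenditure per (sector, fiscal year)
cell, after inflating nominal expenditures to base-year (2014) dollars with
the general Consumer Price Index.  Person-level cost data never cover the
whole budget, so system expenditures outside the hospital/drugs/community
sectors sit in an 'other' sector, which is attributed using the community
care PAF.

Avoided costs compare the actual budget with a counterfactual in which the
baseline-year PAF had persisted: holding the non-attributable budget fixed,
the counterfactual budget is C_t = B_t (1 - PAF_t) / (1 - PAF_0) and the
avoided cost is C_t - B_t, positive when the PAF declined from baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

BASE_YEAR = 2014
SECTORS_WITH_OTHER = ["hospital", "drugs", "community", "other"]
#: sector with no PAF of its own; attributed with community care's PAF
OTHER_SECTOR = "other"
OTHER_PAF_PROXY = "community"


@dataclass(frozen=True)
class CpiSeries:
    """Annual general CPI, normalized so the base-year (2014) index is 1."""

    index: Mapping[int, float]
    base_year: int = BASE_YEAR

    def __post_init__(self):
        if self.base_year not in self.index:
            raise ValueError(f"CPI series must include base year {self.base_year}")
        if any(v <= 0 for v in self.index.values()):
            raise ValueError("CPI index values must be positive")

    def ratio(self, year: int) -> float:
        """Multiplier converting nominal `year` dollars to base-year dollars."""
        if year not in self.index:
            raise KeyError(f"CPI series has no entry for year {year}")
        return self.index[self.base_year] / self.index[year]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.index.items()), columns=["year", "cpi"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CpiSeries":
        return cls(index={int(r.year): float(r.cpi) for r in df.itertuples()})


def inflate_to_2014(amount: float, year: int, cpi: CpiSeries) -> float:
    """Express a nominal `year` amount in base-year (2014) dollars."""
    return amount * cpi.ratio(year)


def deflate_from_2014(amount: float, year: int, cpi: CpiSeries) -> float:
    """Inverse of :func:`inflate_to_2014` (base-year to nominal)."""
    return amount / cpi.ratio(year)


@dataclass
class ExpenditureTable:
    """Annual public expenditures by sector.

    ``data`` has columns year, sector, amount.  ``currency_year`` tags the
    dollar vintage: ``"nominal"`` for as-published amounts, or 2014 once
    inflated — inflation is applied exactly once, enforced by
    :meth:`to_2014` refusing already-inflated tables.
    """

    data: pd.DataFrame
    currency_year: str | int = "nominal"

    def __post_init__(self):
        required = {"year", "sector", "amount"}
        if not required <= set(self.data.columns):
            raise ValueError(f"expenditure table needs columns {sorted(required)}")
        if (self.data["amount"] < 0).any():
            raise ValueError("expenditures must be non-negative")
        for year, grp in self.data.groupby("year"):
            sectors = set(grp["sector"])
            if sectors != set(SECTORS_WITH_OTHER):
                raise ValueError(
                    f"year {year} must have exactly sectors "
                    f"{SECTORS_WITH_OTHER}, got {sorted(sectors)}"
                )

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    def amount(self, sector: str, year: int) -> float:
        m = (self.data["sector"] == sector) & (self.data["year"] == year)
        if not m.any():
            raise KeyError(f"no expenditure for sector={sector}, year={year}")
        return float(self.data.loc[m, "amount"].iloc[0])

    def total(self, year: int) -> float:
        return float(self.data.loc[self.data["year"] == year, "amount"].sum())

    def to_2014(self, cpi: CpiSeries) -> "ExpenditureTable":
        """Return a copy with every amount inflated to 2014 dollars."""
        if self.currency_year == BASE_YEAR:
            raise ValueError("expenditure table is already in 2014 dollars")
        out = self.data.copy()
        out["amount"] = [
            inflate_to_2014(a, int(y), cpi)
            for a, y in zip(out["amount"], out["year"])
        ]
        return ExpenditureTable(out, currency_year=BASE_YEAR)


@dataclass
class BurdenResult:
    """Attributable and avoided costs plus share summaries.

    ``attributable``: tidy frame (risk, sector, year, paf, expenditure,
    attributable) in 2014 CAD.  ``avoided``: tidy frame (risk, year,
    budget, counterfactual, avoided).  ``shares``: per-risk integer-percent
    shares of total attributable and total avoided dollars.
    """

    attributable: pd.DataFrame
    avoided: pd.DataFrame | None = None
    shares: pd.DataFrame | None = None

    def total_attributable(self, risk: str) -> float:
        df = self.attributable
        return float(df.loc[df["risk"] == risk, "attributable"].sum())

    def total_avoided(self, risk: str) -> float:
        if self.avoided is None:
            raise ValueError("avoided costs were not computed")
        df = self.avoided
        return float(df.loc[df["risk"] == risk, "avoided"].sum())


def attribute_expenditure(
    pafs: pd.DataFrame, expenditures: ExpenditureTable
) -> pd.DataFrame:
    """Attributable dollars per (risk, sector, year) cell.

    ``pafs`` is the tidy PAF series (risk, sector, year, paf) covering the
    hospital, drugs and community sectors for every expenditure year; the
    'other' sector is attributed with the community-care PAF.  Expenditures
    must already be in 2014 dollars.
    """
    if expenditures.currency_year != BASE_YEAR:
        raise ValueError(
            "expenditures must be inflated to 2014 dollars before attribution"
        )
    lookup = {
        (r.risk, r.sector, int(r.year)): float(r.paf)
        for r in pafs.itertuples()
    }
    rows = []
    for risk in pafs["risk"].unique():
        for year in expenditures.years:
            for sector in SECTORS_WITH_OTHER:
                paf_sector = OTHER_PAF_PROXY if sector == OTHER_SECTOR else sector
                key = (risk, paf_sector, year)
                if key not in lookup:
                    raise KeyError(
                        f"no PAF for risk={risk}, sector={paf_sector}, "
                        f"year={year}"
                    )
                p = lookup[key]
                amount = expenditures.amount(sector, year)
                rows.append((risk, sector, year, p, amount, p * amount))
    return pd.DataFrame(
        rows,
        columns=["risk", "sector", "year", "paf", "expenditure", "attributable"],
    )


def avoided_costs(
    baseline_paf: float,
    annual_pafs: Mapping[int, float],
    annual_total_budgets: Mapping[int, float],
) -> pd.DataFrame:
    """Avoided dollars from holding the baseline-year PAF constant.

    Counterfactual budget C_t = B_t (1 - PAF_t) / (1 - PAF_0); avoided(t) =
    C_t - B_t, positive exactly when PAF_t < PAF_0.  Returns a tidy frame
    with columns year, budget, counterfactual, avoided.
    """
    if baseline_paf >= 1:
        raise ValueError("baseline PAF must be < 1")
    rows = []
    for year in sorted(annual_total_budgets):
        if year not in annual_pafs:
            raise KeyError(f"no annual PAF for year {year}")
        p_t = annual_pafs[year]
        if p_t >= 1:
            raise ValueError(f"PAF for year {year} must be < 1")
        b_t = annual_total_budgets[year]
        c_t = b_t * (1.0 - p_t) / (1.0 - baseline_paf)
        rows.append((year, b_t, c_t, c_t - b_t))
    return pd.DataFrame(
        rows, columns=["year", "budget", "counterfactual", "avoided"]
    )


def summarize_burden(
    result: BurdenResult, *, risks: list[str] | None = None
) -> pd.DataFrame:
    """Per-risk integer-percent shares of attributable and avoided totals.

    Shares are over the listed single risks (mutually exclusive recodings);
    the combined-behaviour series, which overlaps the single risks, is
    excluded from the denominator.  Zero totals yield NaN shares with a
    warning.
    """
    if risks is None:
        risks = [r for r in result.attributable["risk"].unique() if r != "combined"]
    att = {r: result.total_attributable(r) for r in risks}
    att_total = sum(att.values())
    rows = {}
    if att_total <= 0:
        warnings.warn("total attributable cost is zero; shares undefined")
    for r in risks:
        rows[r] = {
            "attributable": att[r],
            "attributable_share_pct": (
                round(100 * att[r] / att_total) if att_total > 0 else np.nan
            ),
        }
    if result.avoided is not None:
        avd = {r: result.total_avoided(r) for r in risks if
               (result.avoided["risk"] == r).any()}
        avd_total = sum(avd.values())
        if avd and avd_total == 0:
            warnings.warn("total avoided cost is zero; shares undefined")
        for r, v in avd.items():
            rows[r]["avoided"] = v
            rows[r]["avoided_share_pct"] = (
                round(100 * v / avd_total) if avd_total != 0 else np.nan
            )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "risk"
    return out.reset_index()


def sector_shares(attributable: pd.DataFrame, risk: str) -> pd.DataFrame:
    """Integer-percent share of a risk's attributable dollars by sector."""
    df = attributable[attributable["risk"] == risk]
    total = df["attributable"].sum()
    if total <= 0:
        raise ValueError(f"risk {risk!r} has no attributable dollars")
    by_sector = df.groupby("sector")["attributable"].sum()
    out = (100 * by_sector / total).round().astype(int).rename("share_pct")
    return out.reset_index()
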