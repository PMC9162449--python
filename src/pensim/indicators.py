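"""The six fund-reserve indicators, the accumulated-balance recursion,
depletion year, and trend statistics.

Indicator 1: expenditures / contributions (current year).
Indicator 2: contributions - expenditures (trillion yuan).
Indicator 3: current payment gap / contributions (0 while no gap).
Indicator 4: accumulated balance (trillion yuan); positive balances earn the
             ROI, deficits carry forward without interest.
Indicator 5: fund ratio — prior-year-end accumulated balance / current
             expenditures (years of payments covered; 0 once exhausted).
Indicator 6: accumulated gap / contributions (blank while Indicator 4 >= 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .actuarial import FundFlow

__all__ = ["accumulate", "indicator_table", "depletion_year",
           "trend_statistics", "INDICATOR_COLUMNS"]

TRILLION = 1e12
INDICATOR_COLUMNS = ["year", "ind1", "ind2", "ind3", "ind4", "ind5", "ind6",
                     "contributions", "expenditures"]


def accumulate(prev_balance: float, roi: float, flow_balance: float) -> float:
    """One step of the accumulated-balance recursion.

    A positive prior balance is credited the ROI before adding the year's
    flow; a non-positive prior balance carries forward without interest.
    """
    if prev_balance > 0:
        return prev_balance * (1.0 + roi) + flow_balance
    return prev_balance + flow_balance


def indicator_table(flows: list[FundFlow], initial_fund: float,
                    roi_path) -> pd.DataFrame:
    """Per-year indicator table from a fund-flow series.

    ``initial_fund`` is the accumulated balance at the end of the year
    preceding the first flow; ``roi_path`` aligns with ``flows``. Monetary
    columns are reported in trillion yuan. Years with zero contributions get
    missing ratio indicators.
    """
    if not flows:
        raise ValueError("empty flow series")
    roi_path = np.asarray(roi_path, dtype=float)
    if len(roi_path) != len(flows):
        raise ValueError("roi path must align with the flow series")
    rows = []
    acc = initial_fund
    for flow, roi in zip(flows, roi_path):
        prev_acc = acc
        acc = accumulate(acc, roi, flow.balance)
        contrib, exp = flow.contributions, flow.expenditures
        if contrib > 0:
            ind1 = exp / contrib
            ind3 = max(0.0, exp - contrib) / contrib
            ind6 = -acc / contrib if acc < 0 else np.nan
        else:
            ind1 = ind3 = ind6 = np.nan
        ind5 = prev_acc / exp if (prev_acc > 0 and exp > 0) else 0.0
        rows.append({
            "year": flow.year, "ind1": ind1,
            "ind2": (contrib - exp) / TRILLION, "ind3": ind3,
            "ind4": acc / TRILLION, "ind5": ind5, "ind6": ind6,
            "contributions": contrib / TRILLION,
            "expenditures": exp / TRILLION})
    return pd.DataFrame(rows, columns=INDICATOR_COLUMNS)


def depletion_year(table: pd.DataFrame) -> int | None:
    """First year the accumulated balance turns negative, or None."""
    if len(table) == 0:
        raise ValueError("empty indicator table")
    neg = table.loc[table["ind4"] < 0, "year"]
    return int(neg.iloc[0]) if len(neg) else None


def trend_statistics(table: pd.DataFrame) -> dict:
    """Average-annual trend statistics over the forecast period.

    * ind1: geometric average annual growth rate between endpoints;
    * ind2, ind4: average annual change, (end - start) / number of yearly
      steps;
    * ind3, ind6: annual average change rate, (end value - value in the
      first year a gap appears) / years in between (missing when no gap).
    """
    if len(table) < 2:
        raise ValueError("trend statistics need at least two years")
    years = table["year"].to_numpy()
    steps = int(years[-1] - years[0])
    out = {}
    ind1 = table["ind1"].to_numpy(dtype=float)
    out["ind1_avg_growth_rate"] = (ind1[-1] / ind1[0]) ** (1.0 / steps) - 1.0
    for col in ("ind2", "ind4"):
        vals = table[col].to_numpy(dtype=float)
        out[f"{col}_avg_annual_change"] = (vals[-1] - vals[0]) / steps
    for col, gap_mask in (("ind3", table["ind2"].to_numpy() < 0),
                          ("ind6", table["ind4"].to_numpy() < 0)):
        vals = table[col].to_numpy(dtype=float)
        if gap_mask.any():
            first = int(np.argmax(gap_mask))
            span = years[-1] - years[first]
            out[f"{col}_avg_change_rate"] = (
                (vals[-1] - vals[first]) / span if span > 0 else np.nan)
        else:
            out[f"{col}_avg_change_rate"] = np.nan
    return out
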