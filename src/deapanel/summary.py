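"""Yearly and regional aggregation of efficiency estimates.

Produces the series behind the study's headline figures: per-year means
of raw and bias-corrected scores with normal-approximation confidence
intervals, per-region means for reported anchor years, growth rates over
the panel window (truncated, not rounded, to two decimals), an OLS trend
test per region, and a one-way ANOVA between-region difference test per
year.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def summarize_years(estimates: pd.DataFrame) -> pd.DataFrame:
    """Per-year mean raw/corrected efficiency with SE and 95% CI.

    A year with a single estimate has no SE; its CI collapses to the
    point and is flagged in the ``degenerate`` column.  SE uses the
    population SD (ddof=0) convention throughout this module.
    """
    if estimates.empty:
        raise ValueError("no estimates to summarize")
    rows = []
    for year, sl in estimates.groupby("year", sort=True):
        n = len(sl)
        mean_c = sl["bias_corrected_efficiency"].mean()
        if n > 1:
            se = sl["bias_corrected_efficiency"].std(ddof=0) / math.sqrt(n)
        else:
            se = float("nan")
        half = Z95 * se if n > 1 else 0.0
        rows.append(
            {
                "year": year,
                "mean_raw": sl["raw_efficiency"].mean(),
                "mean_corrected": mean_c,
                "se_corrected": se,
                "ci_low": mean_c - half,
                "ci_high": mean_c + half,
                "n": n,
                "degenerate": n == 1,
            }
        )
    return pd.DataFrame(rows)


def growth_rate(start_mean: float, end_mean: float) -> float:
    """Percent change 100*(end-start)/start, truncated toward zero at 2 decimals.

    Truncation (not rounding) is the convention that reproduces published
    two-decimal growth rates such as 31.42 (from 31.4286) and 66.66 (from
    66.667).
    """
    if start_mean <= 0:
        raise ValueError("start mean must be positive")
    pct = 100.0 * (end_mean - start_mean) / start_mean
    # guard against float error just below a two-decimal boundary
    return math.trunc(round(pct * 100, 6)) / 100.0


def trend_test(scores: np.ndarray | pd.Series, years: np.ndarray | pd.Series) -> float:
    """Two-sided p-value for the OLS slope of score on year."""
    years = np.asarray(years, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if np.unique(years).size < 3:
        raise ValueError("need at least 3 distinct years for a trend test")
    if np.ptp(scores) == 0:
        return 1.0  # flat series: slope exactly 0
    return float(stats.linregress(years, scores).pvalue)


def region_difference_test(groups: list[np.ndarray]) -> float:
    """One-way ANOVA p-value across regions within one year."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 regions with >= 2 scores each")
    if np.ptp(np.concatenate(groups)) == 0:
        return 1.0  # all scores identical: no between-region signal
    return float(stats.f_oneway(*groups).pvalue)


def summarize_regions(
    estimates: pd.DataFrame,
    report_years: tuple[int, ...] = (2009, 2015, 2020),
) -> pd.DataFrame:
    """Region-level table: anchor-year means (SD), growth rate, trend p-value.

    Region 0 aggregates all jurisdictions so the overall row comes from
    the same code path as regions 1..k.  The growth rate runs from the
    first to the last reported year and is computed from this table's own
    (unrounded) means under the truncation convention.
    """
    if "region" not in estimates.columns:
        raise ValueError("estimates need a 'region' column")
    avail = sorted(set(estimates["year"]))
    use_years = [y for y in report_years if y in avail]
    if len(use_years) < 2:
        use_years = [min(avail), max(avail)]
    rows = []
    regions = [0] + sorted(int(r) for r in estimates["region"].dropna().unique())
    for reg in regions:
        sl = estimates if reg == 0 else estimates[estimates["region"] == reg]
        row: dict = {"region": reg}
        for y in use_years:
            scores = sl.loc[sl["year"] == y, "bias_corrected_efficiency"]
            row[f"mean_{y}"] = scores.mean()
            row[f"sd_{y}"] = scores.std(ddof=0)
        row["growth_rate_pct"] = growth_rate(
            row[f"mean_{use_years[0]}"], row[f"mean_{use_years[-1]}"]
        )
        row["trend_p"] = trend_test(
            sl["bias_corrected_efficiency"], sl["year"]
        )
        rows.append(row)
    return pd.DataFrame(rows)


def region_difference_by_year(estimates: pd.DataFrame) -> pd.DataFrame:
    """ANOVA p-value across regions for every year with enough data."""
    rows = []
    for year, sl in estimates.groupby("year", sort=True):
        groups = [
            g["bias_corrected_efficiency"].to_numpy()
            for _, g in sl.groupby("region")
            if len(g) >= 2
        ]
        if len(groups) >= 2:
            rows.append({"year": year, "p_value": region_difference_test(groups)})
    return pd.DataFrame(rows)


def format_region_table(
    region_table: pd.DataFrame,
    difference_by_year: pd.DataFrame | None = None,
) -> str:
    """Plain-text report of the regional summary (overall row first)."""
    year_cols = [c for c in region_table.columns if c.startswith("mean_")]
    years = [int(c.split("_")[1]) for c in year_cols]
    lines = []
    header = ["Region".ljust(18)] + [f"{y} mean (SD)".rjust(18) for y in years]
    header += ["Growth rate %".rjust(14), "P for trend".rjust(12)]
    lines.append("".join(header))
    for _, row in region_table.iterrows():
        label = "All jurisdictions" if row["region"] == 0 else f"Region {int(row['region'])}"
        cells = [label.ljust(18)]
        for y in years:
            cells.append(f"{row[f'mean_{y}']:.2f} ({row[f'sd_{y}']:.2f})".rjust(18))
        cells.append(f"{row['growth_rate_pct']:.2f}".rjust(14))
        p = row["trend_p"]
        cells.append(("<0.01" if p < 0.01 else f"{p:.2f}").rjust(12))
        lines.append("".join(cells))
    if difference_by_year is not None and not difference_by_year.empty:
        ps = {int(r.year): r.p_value for r in difference_by_year.itertuples()}
        cells = ["Region diff (P)".ljust(18)]
        for y in years:
            p = ps.get(y)
            cells.append(
                ("-" if p is None else "<0.01" if p < 0.01 else f"{p:.2f}").rjust(18)
            )
        lines.append("".join(cells))
    return "\n".join(lines)
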