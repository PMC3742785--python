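"""Descriptive oxygen statistics and metabolism–driver relationships.

Daily summaries flag hypoxia at the conventional 2 mg L⁻¹ threshold and
express DO relative to temperature-dependent saturation; monthly
aggregates average usable days (rates only over days passing the
sufficiency filter); correlations between monthly metabolism and
physical drivers use Pearson's r with a Student-t test, and daily-scale
relationships use tie-corrected Kendall's τ-b.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gas_exchange import o2_saturation
from .types import SiteMeta, SondeSeries

__all__ = [
    "HYPOXIA_MGL",
    "oxygen_summaries",
    "combine_daily",
    "monthly_aggregate",
    "pearson_with_test",
    "kendall_tau",
    "correlation_matrix",
]

HYPOXIA_MGL = 2.0


def oxygen_summaries(series: SondeSeries, site: Optional[SiteMeta] = None,
                     pressure_atm: float = 1.0) -> pd.DataFrame:
    """Per-calendar-day oxygen statistics.

    Columns: ``mean_do``, ``min_do``, ``pct_sat_mean`` (mean of per-step
    percent saturation), ``hypoxic_day`` (daily mean < 2 mg L⁻¹),
    ``hypoxic_any`` (any step < 2), ``below_sat_mean`` /
    ``below_sat_all`` (daily-mean below 100% saturation / every step
    below), plus daily means of the driver columns present.
    """
    df = series.data.copy()
    sat = o2_saturation(df["temp_C"].to_numpy(), pressure_atm)
    df["pct_sat"] = 100.0 * df["do_mgL"].to_numpy() / sat
    g = df.groupby(df.index.normalize())
    out = pd.DataFrame({
        "mean_do": g["do_mgL"].mean(),
        "min_do": g["do_mgL"].min(),
        "pct_sat_mean": g["pct_sat"].mean(),
        "hypoxic_any": g["do_mgL"].min() < HYPOXIA_MGL,
        "below_sat_all": g["pct_sat"].max() < 100.0,
        "mean_temp": g["temp_C"].mean(),
        "n_obs": g["do_mgL"].count(),
    })
    out["hypoxic_day"] = out["mean_do"] < HYPOXIA_MGL
    out["below_sat_mean"] = out["pct_sat_mean"] < 100.0
    for col in ("turbidity_NTU", "sp_cond"):
        if col in df.columns:
            out[f"mean_{col}"] = g[col].mean()
    out.index.name = "date"
    return out


def combine_daily(oxygen: pd.DataFrame, rates: pd.DataFrame) -> pd.DataFrame:
    """Join per-day oxygen statistics with fitted rate summaries on date."""
    r = rates.copy()
    if "date" in r.columns:
        r = r.set_index(pd.DatetimeIndex(r["date"]).normalize()).drop(columns="date")
    return oxygen.join(r, how="outer")


def monthly_aggregate(daily: pd.DataFrame, lake_level: Optional[pd.Series] = None
                      ) -> pd.DataFrame:
    """Arithmetic monthly means of a combined daily table.

    Rate fields (``gpp_med``, ``er_med``, ``er_gpp_ratio``) average only
    days passing the sufficiency filter (column ``sufficient`` if
    present); driver/oxygen fields average all days. ``lake_level`` is
    an optional external daily series joined before aggregation.
    """
    df = daily.copy()
    if lake_level is not None:
        df["lake_level"] = lake_level.reindex(df.index)
    month = df.index.to_period("M")
    rate_cols = [c for c in ("gpp_med", "er_med", "er_gpp_ratio") if c in df.columns]
    skip = set(rate_cols) | {"sufficient", "converged"}
    other = [c for c in df.columns
             if c not in skip
             and (np.issubdtype(df[c].dtype, np.number) or df[c].dtype == bool)]

    agg = df[other].astype(float).groupby(month).mean()
    agg["n_days"] = df.groupby(month).size()
    if rate_cols:
        if "sufficient" in df.columns:
            suff = df["sufficient"].fillna(False).astype(bool)
        else:
            suff = pd.Series(True, index=df.index)
        sub = df.loc[suff, rate_cols]
        rates = sub.groupby(month[suff.to_numpy()]).mean()
        agg = agg.join(rates, how="left")
        counts = df.loc[suff].groupby(month[suff.to_numpy()]).size()
        agg["n_sufficient"] = counts.reindex(agg.index).fillna(0).astype(int)
    agg.index.name = "month"
    return agg


def pearson_with_test(x, y, alpha: float = 0.05):
    """Sample Pearson r with a two-sided Student-t test on n−2 df.

    Returns ``(r, p, significant)``; raises on fewer than 3 finite pairs
    or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def kendall_tau(x, y):
    """Tie-corrected Kendall τ-b with p-value.

    Exact enumeration of the null for n ≤ 10 without ties, otherwise the
    normal approximation. Raises on all-tied input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite pairs")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise ValueError("Kendall tau undefined for all-tied input")
    has_ties = len(np.unique(x)) < len(x) or len(np.unique(y)) < len(y)
    method = "exact" if (len(x) <= 10 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(monthly: pd.DataFrame,
                       metabolism_cols: Sequence[str] = ("gpp_med", "er_med", "er_gpp_ratio"),
                       driver_cols: Sequence[str] = ("lake_level", "mean_do", "mean_temp",
                                                     "mean_turbidity_NTU", "mean_sp_cond"),
                       method: str = "pearson",
                       min_sufficient_days: int = 3) -> pd.DataFrame:
    """Pairwise metabolism-vs-driver correlations over monthly averages.

    Months with fewer than ``min_sufficient_days`` sufficient days are
    excluded (a monthly mean of 1–2 days is unstable); drivers absent
    from the table are skipped. Returns long-form rows of
    (metabolism, driver, stat, p, n, significant).
    """
    df = monthly
    if "n_sufficient" in df.columns:
        df = df[df["n_sufficient"] >= min_sufficient_days]
    rows = []
    for m in metabolism_cols:
        if m not in df.columns:
            continue
        for drv in driver_cols:
            if drv not in df.columns:
                continue
            pair = df[[m, drv]].dropna()
            if len(pair) < 3 or pair[m].std() == 0 or pair[drv].std() == 0:
                continue
            if method == "pearson":
                r, p, sig = pearson_with_test(pair[m], pair[drv])
            else:
                r, p = kendall_tau(pair[m], pair[drv])
                sig = p < 0.05
            rows.append({"metabolism": m, "driver": drv, "stat": r,
                         "p": p, "n": len(pair), "significant": sig})
    return pd.DataFrame(rows)
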