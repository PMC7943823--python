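"""Closed-form micrometeorology for the understory climate series.

Saturation vapour pressure follows Bolton's approximation,
e_s = 6.112 * exp(17.67*T / (T + 243.5)) hPa, and vapour pressure deficit is
VPD = ((100 - RH)/100) * e_s.  Monthly aggregation computes VPD per record
before averaging (the mean of a convex function is not the function of the
mean), running precipitation is a trailing 30-day sum, and the ENSO anomaly
compares an event month against the calendar mean of baseline years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "saturation_vapour_pressure",
    "vpd",
    "monthly_means",
    "running_precip",
    "enso_anomaly",
]


def saturation_vapour_pressure(t_c):
    """Saturation vapour pressure e_s (hPa) at air temperature t_c (degC)."""
    t = np.asarray(t_c, dtype=float)
    if np.any(t <= -243.5):
        raise ValueError("temperature must exceed -243.5 degC")
    return 6.112 * np.exp(17.67 * t / (t + 243.5))


def vpd(t_c, rh_pct):
    """Vapour pressure deficit (hPa): ((100 - RH)/100) * e_s(T)."""
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity must lie in [0, 100]")
    return (100.0 - rh) / 100.0 * saturation_vapour_pressure(t_c)


def monthly_means(series: pd.DataFrame) -> pd.DataFrame:
    """Monthly mean temperature and VPD, per plot when a plot_id column exists.

    VPD is computed record by record and then averaged.  Months without any
    record are simply absent from the output.
    """
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["vpd_hpa"] = vpd(df["t_c"].to_numpy(float), df["rh_pct"].to_numpy(float))
    df["month"] = df["date"].dt.to_period("M")
    keys = ["plot_id", "month"] if "plot_id" in df.columns else ["month"]
    out = df.groupby(keys, as_index=False)[["t_c", "vpd_hpa"]].mean()
    return out.rename(columns={"t_c": "t_mean_c", "vpd_hpa": "vpd_mean_hpa"})


def running_precip(daily: pd.DataFrame, window_days: int = 30) -> pd.DataFrame:
    """Trailing ``window_days``-day precipitation sum (mm).

    The first window-1 days are undefined, as is any window containing a
    missing day (the series is reindexed to a continuous daily calendar and
    gaps become NaN).
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.set_index("date").sort_index()
    full = pd.date_range(df.index.min(), df.index.max(), freq="D")
    precip = df["precip_mm"].reindex(full)
    out = precip.rolling(window_days, min_periods=window_days).sum()
    return pd.DataFrame({"date": full, "precip_mm_running": out.to_numpy()})


def enso_anomaly(
    monthly: pd.DataFrame, event_month: str, baseline_years: tuple[int, ...] = (2013, 2014)
) -> dict:
    """Event-month anomalies relative to the baseline (non-event) years.

    dT (degC) is the event-month mean temperature minus the mean of monthly
    temperatures over all months of the baseline years; dVPD_pct is the
    corresponding VPD difference as a percentage of the baseline VPD.
    """
    df = monthly.copy()
    df["month"] = pd.PeriodIndex(df["month"], freq="M")
    ev = pd.Period(event_month, freq="M")
    event_rows = df[df["month"] == ev]
    if len(event_rows) == 0:
        raise ValueError(f"event month {event_month} absent from the monthly table")
    base_rows = df[df["month"].dt.year.isin(baseline_years)]
    if len(base_rows) == 0:
        raise ValueError(f"no baseline months in years {baseline_years}")
    t_event = float(event_rows["t_mean_c"].mean())
    v_event = float(event_rows["vpd_mean_hpa"].mean())
    t_base = float(base_rows["t_mean_c"].mean())
    v_base = float(base_rows["vpd_mean_hpa"].mean())
    return {
        "dT_c": t_event - t_base,
        "dVPD_pct": 100.0 * (v_event - v_base) / v_base,
        "baseline_t_c": t_base,
        "baseline_vpd_hpa": v_base,
    }
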