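"""In-situ thermal stress indices for reef monitoring.

Builds a monthly climatology from depth-stratified temperature-logger
records and computes the two standard coral stress metrics on daily mean
temperatures:

* **HotSpot** — the positive daily anomaly above the maximum monthly mean
  (MMM) of the climatology, in °C.
* **Degree Heating Weeks (DHW)** — the trailing-window accumulation of
  HotSpots at or above an accumulation floor, divided by 7, in °C-weeks.

Thermal stress conditions are flagged at HotSpot >= 2.0 °C and bleaching
risk at DHW >= 4.0 °C-weeks; maximal runs of days over either threshold are
reported as events.  Depth channels are processed independently.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TEMP_MIN_C",
    "TEMP_MAX_C",
    "STRESS_HOTSPOT_C",
    "RISK_DHW_CWEEKS",
    "Climatology",
    "ThermalEvent",
    "ThermalError",
    "EmptySeriesError",
    "IncompleteClimatologyError",
    "ChannelMismatchError",
    "OrderingError",
    "read_temperature_table",
    "aggregate_daily",
    "build_climatology",
    "hotspot",
    "degree_heating_weeks",
    "detect_events",
    "analyze",
]

#: plausibility bounds for a tropical reef logger; readings outside are rejected
TEMP_MIN_C = 15.0
TEMP_MAX_C = 40.0

#: HotSpot level defining thermal stress conditions (°C above MMM)
STRESS_HOTSPOT_C = 2.0

#: DHW level defining the onset of bleaching risk (°C-weeks)
RISK_DHW_CWEEKS = 4.0


class ThermalError(ValueError):
    """Base class for thermal-module errors."""


class EmptySeriesError(ThermalError):
    """All readings were rejected, or an empty series was supplied."""


class IncompleteClimatologyError(ThermalError):
    """A calendar month has no data in the baseline years."""


class ChannelMismatchError(ThermalError):
    """The requested depth channel is absent from the series."""


class OrderingError(ThermalError):
    """Dates within a depth channel are not strictly increasing."""


@dataclass(frozen=True)
class Climatology:
    """Monthly mean climatology for one depth channel.

    ``mmm_C`` is the maximum of the twelve monthly means and is the
    reference temperature for the HotSpot anomaly.
    """

    depth_m: float
    monthly_mean_C: tuple  # 12 values, Jan..Dec
    mmm_C: float
    baseline_years: tuple  # (first_year, last_year)

    def __post_init__(self):
        if len(self.monthly_mean_C) != 12:
            raise ThermalError("climatology needs 12 monthly means")
        if not np.isclose(self.mmm_C, max(self.monthly_mean_C)):
            raise ThermalError("mmm_C must equal the maximum monthly mean")


@dataclass(frozen=True)
class ThermalEvent:
    depth_m: float
    start_date: _dt.date
    end_date: _dt.date
    peak_hotspot_C: float
    peak_dhw_Cweeks: float
    severity: str  # "stress" or "bleaching_risk"

    def __post_init__(self):
        if self.start_date > self.end_date:
            raise ThermalError("event start after end")
        if self.severity not in ("stress", "bleaching_risk"):
            raise ThermalError(f"unknown severity {self.severity!r}")


def read_temperature_table(path) -> pd.DataFrame:
    """Read a delimited logger table with columns timestamp, depth_m, temp_C."""
    df = pd.read_csv(path)
    missing = {"timestamp", "depth_m", "temp_C"} - set(df.columns)
    if missing:
        raise ThermalError(f"temperature table missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def aggregate_daily(
    readings: pd.DataFrame,
    temp_min_C: float = TEMP_MIN_C,
    temp_max_C: float = TEMP_MAX_C,
) -> pd.DataFrame:
    """Collapse sub-daily logger readings to daily means per depth channel.

    Readings outside ``[temp_min_C, temp_max_C]`` are rejected as logger
    glitches.  Returns one row per (date, depth) with columns ``date``,
    ``depth_m``, ``mean_temp_C``, ``n_readings``; days with no valid
    readings are simply absent.
    """
    if readings is None or len(readings) == 0:
        raise EmptySeriesError("no temperature readings supplied")
    df = readings.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    ok = (df["temp_C"] >= temp_min_C) & (df["temp_C"] <= temp_max_C)
    df = df[ok]
    if len(df) == 0:
        raise EmptySeriesError("all temperature readings were rejected as out of range")
    df["date"] = df["timestamp"].dt.normalize()
    out = (
        df.groupby(["date", "depth_m"], as_index=False)
        .agg(mean_temp_C=("temp_C", "mean"), n_readings=("temp_C", "size"))
        .sort_values(["depth_m", "date"], ignore_index=True)
    )
    return out[["date", "depth_m", "mean_temp_C", "n_readings"]]


def _channel(daily: pd.DataFrame, depth_m: float | None) -> tuple[pd.DataFrame, float]:
    depths = sorted(daily["depth_m"].unique())
    if depth_m is None:
        if len(depths) != 1:
            raise ChannelMismatchError(
                f"series holds depths {depths}; specify depth_m explicitly"
            )
        depth_m = depths[0]
    sub = daily[daily["depth_m"] == depth_m]
    if len(sub) == 0:
        raise ChannelMismatchError(f"no data for depth {depth_m} m (have {depths})")
    return sub.sort_values("date"), float(depth_m)


def build_climatology(
    daily: pd.DataFrame,
    depth_m: float | None = None,
    baseline_years: tuple[int, int] | None = None,
) -> Climatology:
    """Pool daily means by calendar month over the baseline years.

    ``baseline_years`` is an inclusive ``(first, last)`` range; the default
    uses the entire provided record.  Every calendar month must be
    represented at least once, otherwise :class:`IncompleteClimatologyError`
    names the missing month.
    """
    sub, depth_m = _channel(daily, depth_m)
    dates = pd.DatetimeIndex(sub["date"])
    years = dates.year
    if baseline_years is not None:
        y0, y1 = baseline_years
        mask = (years >= y0) & (years <= y1)
        if not mask.any():
            raise EmptySeriesError(f"no data within baseline years {y0}-{y1}")
        sub = sub[np.asarray(mask)]
        dates = pd.DatetimeIndex(sub["date"])
    months = dates.month
    temps = sub["mean_temp_C"].to_numpy()
    monthly = np.empty(12)
    for m in range(1, 13):
        vals = temps[months == m]
        if vals.size == 0:
            raise IncompleteClimatologyError(
                f"no baseline data for {calendar.month_name[m]}"
            )
        monthly[m - 1] = vals.mean()
    return Climatology(
        depth_m=depth_m,
        monthly_mean_C=tuple(monthly),
        mmm_C=float(monthly.max()),
        baseline_years=(int(dates.year.min()), int(dates.year.max())),
    )


def hotspot(daily: pd.DataFrame, clim: Climatology) -> pd.DataFrame:
    """Positive daily anomaly above the climatological MMM, clamped at zero."""
    sub, _ = _channel(daily, clim.depth_m)
    out = sub.copy()
    out["hotspot_C"] = np.maximum(0.0, out["mean_temp_C"].to_numpy() - clim.mmm_C)
    return out.reset_index(drop=True)


def degree_heating_weeks(
    stress: pd.DataFrame,
    window_days: int = 84,
    accum_min_C: float = 1.0,
    max_gap_fraction: float = 0.1,
) -> pd.DataFrame:
    """Trailing-window accumulation of HotSpots, in °C-weeks.

    ``dhw(d)`` is the sum, over the ``window_days`` days ending at ``d``, of
    HotSpot values at or above ``accum_min_C``, divided by 7.  Days whose
    trailing window extends before the start of the record are flagged
    ``dhw_incomplete``; days with more than ``max_gap_fraction`` of the
    window missing from the record are flagged ``dhw_gap_affected`` (the
    accumulation is computed over the available days).
    """
    if "hotspot_C" not in stress.columns:
        raise ThermalError("hotspot_C must be computed before DHW")
    if window_days < 7:
        raise ThermalError("window_days must be >= 7")
    parts = []
    for depth, g in stress.groupby("depth_m", sort=True):
        dates = pd.DatetimeIndex(pd.to_datetime(g["date"]))
        if not dates.is_monotonic_increasing or dates.has_duplicates:
            raise OrderingError(f"dates not strictly increasing for depth {depth} m")
        g = g.set_index(dates)
        full_idx = pd.date_range(dates[0], dates[-1], freq="D")
        full = g.reindex(full_idx)
        present = full["hotspot_C"].notna()
        hs = full["hotspot_C"].fillna(0.0)
        contrib = hs.where(hs >= accum_min_C, 0.0)
        dhw = contrib.rolling(window_days, min_periods=1).sum() / 7.0
        n_missing = (~present).astype(float).rolling(window_days, min_periods=1).sum()
        elapsed = (full_idx - full_idx[0]).days + 1
        incomplete = elapsed < window_days
        gap = n_missing.to_numpy() / float(window_days) > max_gap_fraction
        res = full[present.to_numpy()].copy()
        res["dhw_Cweeks"] = dhw[present.to_numpy()].to_numpy()
        res["dhw_incomplete"] = incomplete[present.to_numpy()]
        res["dhw_gap_affected"] = gap[present.to_numpy()]
        res["date"] = res.index
        parts.append(res.reset_index(drop=True))
    return pd.concat(parts, ignore_index=True)


def _runs(dates: np.ndarray, mask: np.ndarray) -> Iterable[tuple[int, int]]:
    """Maximal runs of True in ``mask`` over calendar-contiguous dates."""
    start = None
    for i in range(len(mask)):
        contiguous = i > 0 and (dates[i] - dates[i - 1]) == np.timedelta64(1, "D")
        if mask[i] and (start is None):
            start = i
        elif start is not None and mask[i] and not contiguous:
            yield start, i - 1
            start = i
        elif start is not None and not mask[i]:
            yield start, i - 1
            start = None
    if start is not None:
        yield start, len(mask) - 1


def detect_events(
    stress: pd.DataFrame,
    stress_hotspot_C: float = STRESS_HOTSPOT_C,
    risk_dhw_Cweeks: float = RISK_DHW_CWEEKS,
) -> list[ThermalEvent]:
    """Maximal runs of days over the stress and bleaching-risk thresholds."""
    if "dhw_Cweeks" not in stress.columns:
        raise ThermalError("dhw_Cweeks must be computed before event detection")
    events: list[ThermalEvent] = []
    for depth, g in stress.groupby("depth_m", sort=True):
        g = g.sort_values("date")
        dates = pd.DatetimeIndex(g["date"]).to_numpy(dtype="datetime64[D]")
        hs = g["hotspot_C"].to_numpy()
        dhw = g["dhw_Cweeks"].to_numpy()
        for severity, mask in (
            ("stress", hs >= stress_hotspot_C),
            ("bleaching_risk", dhw >= risk_dhw_Cweeks),
        ):
            for i0, i1 in _runs(dates, mask):
                events.append(
                    ThermalEvent(
                        depth_m=float(depth),
                        start_date=dates[i0].astype(_dt.date),
                        end_date=dates[i1].astype(_dt.date),
                        peak_hotspot_C=float(hs[i0 : i1 + 1].max()),
                        peak_dhw_Cweeks=float(dhw[i0 : i1 + 1].max()),
                        severity=severity,
                    )
                )
    events.sort(key=lambda e: (e.depth_m, e.start_date, e.severity))
    return events


def analyze(
    daily: pd.DataFrame,
    window_days: int = 84,
    accum_min_C: float = 1.0,
    baseline_years: tuple[int, int] | None = None,
    stress_hotspot_C: float = STRESS_HOTSPOT_C,
    risk_dhw_Cweeks: float = RISK_DHW_CWEEKS,
) -> tuple[pd.DataFrame, list[ThermalEvent], dict[float, Climatology]]:
    """Full stress analysis over every depth channel of a daily series.

    Returns the stress series (hotspot + DHW columns), the detected events,
    and the per-depth climatologies.
    """
    parts = []
    clims: dict[float, Climatology] = {}
    for depth in sorted(daily["depth_m"].unique()):
        clim = build_climatology(daily, depth, baseline_years)
        clims[float(depth)] = clim
        parts.append(hotspot(daily, clim))
    stress = degree_heating_weeks(
        pd.concat(parts, ignore_index=True), window_days, accum_min_C
    )
    events = detect_events(stress, stress_hotspot_C, risk_dhw_Cweeks)
    return stress, events, clims
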