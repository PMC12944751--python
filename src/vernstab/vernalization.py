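"""Vernalization-intensity accumulation from daily weather.

Daily minimum/maximum temperatures are interpolated to hourly values with a
sine curve, each hourly temperature is converted to a vernalization weight
(effective only between 0 and 13 °C), days warm enough to devernalize
(tmax > 23 °C) are excluded, and the weighted hours are accumulated from
sowing to the end of accumulation (default June 30) to give the
vernalization intensity an environment delivered — the regressor of the
biphasic bolting model.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

#: temperature window (°C) inside which an hour can vernalize
VERN_WINDOW: tuple[float, float] = (0.0, 13.0)
#: daily maximum (°C) above which the whole day is excluded (devernalization)
DEVERN_TMAX: float = 23.0
#: default hour of the daily temperature maximum
DEFAULT_HX: float = 15.0


@dataclasses.dataclass(frozen=True)
class DailyWeather:
    """One day of weather at one site."""

    date: dt.date
    tmin: float
    tmax: float
    site: str = ""

    def __post_init__(self) -> None:
        if self.tmin > self.tmax:
            raise ValueError(
                f"tmin ({self.tmin}) > tmax ({self.tmax}) on {self.date}"
            )


@dataclasses.dataclass(frozen=True)
class HourlyCurve:
    """24 hourly temperatures for one day (hours 1..24)."""

    date: dt.date
    hours: np.ndarray
    temps: np.ndarray


def hourly_temperatures(day: DailyWeather, hx: float = DEFAULT_HX) -> HourlyCurve:
    """Sine interpolation of hourly temperature from the daily extremes.

    T(h) = Tm + Ta * sin(pi/12 * (h - hx + 6)) with Tm the midpoint of the
    daily range, Ta half the range, and hx the hour of the daily maximum, so
    that T(hx) = tmax and T(hx - 12) = tmin.
    """
    if not 0.0 <= hx <= 24.0:
        raise ValueError(f"hx must be in [0, 24], got {hx}")
    tm = (day.tmin + day.tmax) / 2.0
    ta = (day.tmax - day.tmin) / 2.0
    hours = np.arange(1, 25, dtype=float)
    temps = tm + ta * np.sin(np.pi / 12.0 * (hours - hx + 6.0))
    return HourlyCurve(date=day.date, hours=hours, temps=temps)


def vernalization_weight(x):
    """Vernalization weight of an hourly temperature ``x`` (°C).

    w(x) = max(0, -1.256 + (1.260 + 0.131 x) * 0.9357**x) inside the 0-13 °C
    window and 0 outside it.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    w = -1.256 + (1.260 + 0.131 * x) * np.power(0.9357, x)
    w = np.maximum(w, 0.0)
    lo, hi = VERN_WINDOW
    w = np.where((x >= lo) & (x <= hi), w, 0.0)
    return w if w.ndim else float(w)


def daily_vernalizing_hours(
    curve: HourlyCurve,
    day: DailyWeather,
    devern_tmax: float = DEVERN_TMAX,
) -> tuple[float, bool]:
    """Weighted vernalizing hours of one day and its exclusion flag.

    Returns ``(0.0, True)`` when the daily maximum exceeds the
    devernalization cutoff; otherwise the sum of hourly weights and False.
    """
    if day.tmax > devern_tmax:
        return 0.0, True
    return float(np.sum(vernalization_weight(curve.temps))), False


def vernalization_series(
    days: Iterable[DailyWeather],
    hx: float = DEFAULT_HX,
    devern_tmax: float = DEVERN_TMAX,
) -> pd.DataFrame:
    """Per-day weighted hours, exclusion flags and running intensity.

    Returns a DataFrame indexed by date with columns ``weighted_hours``,
    ``excluded`` and ``cumulative`` (running sum of weighted hours).
    """
    records = []
    for day in days:
        wh, excl = daily_vernalizing_hours(
            hourly_temperatures(day, hx=hx), day, devern_tmax=devern_tmax
        )
        records.append((day.date, wh, excl))
    df = pd.DataFrame(records, columns=["date", "weighted_hours", "excluded"])
    df = df.set_index("date").sort_index()
    df["cumulative"] = df["weighted_hours"].cumsum()
    return df


class WeatherGapError(ValueError):
    """Raised when the weather series does not cover the requested window."""

    def __init__(self, missing: Sequence[dt.date]):
        self.missing = list(missing)
        shown = ", ".join(str(d) for d in self.missing[:10])
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"weather series missing dates: {shown}{more}")


def cumulative_intensity(
    days: Iterable[DailyWeather],
    sowing_date: dt.date,
    end_date: dt.date,
    hx: float = DEFAULT_HX,
    devern_tmax: float = DEVERN_TMAX,
) -> float:
    """Vernalization intensity accumulated over [sowing_date, end_date].

    Both endpoints are inclusive.  Raises :class:`WeatherGapError` if any day
    in the window has no weather record.
    """
    if sowing_date > end_date:
        raise ValueError("sowing_date must not be after end_date")
    series = vernalization_series(days, hx=hx, devern_tmax=devern_tmax)
    wanted = pd.date_range(sowing_date, end_date, freq="D").date
    have = set(series.index)
    missing = [d for d in wanted if d not in have]
    if missing:
        raise WeatherGapError(missing)
    window = series.loc[list(wanted)]
    return float(window["weighted_hours"].sum())
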