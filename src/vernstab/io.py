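"""Readers, writers and run configuration.

Canonical interchange is CSV; XLSX files of the same schema are accepted
read-only.  Weather tables carry (date, tmin, tmax, site); trial tables
carry (year, location, block, genotype, ry, sc, na, k, n, bolting_pct) with
impurities in meq/100 g and the environment key formed as location x year.
Row-level validation errors are collected and reported with line numbers
rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from pathlib import Path

import pandas as pd

from .vernalization import DEFAULT_HX, DEVERN_TMAX, VERN_WINDOW, DailyWeather

WEATHER_COLUMNS = ["date", "tmin", "tmax", "site"]
TRIAL_COLUMNS = [
    "year",
    "location",
    "block",
    "genotype",
    "ry",
    "sc",
    "na",
    "k",
    "n",
    "bolting_pct",
]
#: traits analysed by the MET stages, in report order
MET_TRAITS = ["wsy", "ry", "sc", "na", "k", "n"]
#: default improvement direction per trait
DEFAULT_GOALS = {
    "ry": "increase",
    "sc": "increase",
    "na": "decrease",
    "k": "decrease",
    "n": "decrease",
    "bolting_pct": "decrease",
}


class ValidationError(ValueError):
    """File-level validation failure with row detail."""

    def __init__(self, path, problems):
        self.path = str(path)
        self.problems = list(problems)
        shown = "; ".join(self.problems[:10])
        more = "" if len(self.problems) <= 10 else f" (+{len(self.problems) - 10} more)"
        super().__init__(f"{path}: {shown}{more}")


def _read_table(path: Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_weather(path) -> pd.DataFrame:
    """Validated weather table; raises :class:`ValidationError` on bad rows."""
    df = _read_table(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(path, [f"missing columns: {missing}"])
    problems = []
    dates = pd.to_datetime(df["date"], errors="coerce")
    for i in df.index[dates.isna()]:
        problems.append(f"row {i + 2}: unparseable date {df.loc[i, 'date']!r}")
    bad = df.index[df["tmin"] > df["tmax"]]
    for i in bad:
        problems.append(
            f"row {i + 2}: tmin ({df.loc[i, 'tmin']}) > tmax ({df.loc[i, 'tmax']})"
        )
    dup = df.assign(_d=dates).duplicated(subset=["site", "_d"], keep=False)
    if dup.any():
        problems.append(f"duplicate (site, date) rows: {list(df.index[dup][:5])}")
    if problems:
        raise ValidationError(path, problems)
    out = df[WEATHER_COLUMNS].copy()
    out["date"] = dates.dt.date
    return out


def weather_to_days(df: pd.DataFrame, site: str) -> list[DailyWeather]:
    sub = df[df["site"] == site].sort_values("date")
    return [
        DailyWeather(date=r.date, tmin=float(r.tmin), tmax=float(r.tmax), site=site)
        for r in sub.itertuples(index=False)
    ]


def write_weather(df: pd.DataFrame, path) -> None:
    df[WEATHER_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Validated trial table with an ``environment`` (location x year) key."""
    df = _read_table(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(path, [f"missing columns: {missing}"])
    problems = []
    for col in ("ry", "sc", "na", "k", "n"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[vals.isna() & df[col].notna()]:
            problems.append(f"row {i + 2}: non-numeric {col}: {df.loc[i, col]!r}")
        for i in df.index[vals < 0]:
            problems.append(f"row {i + 2}: negative {col}: {df.loc[i, col]!r}")
    bp = pd.to_numeric(df["bolting_pct"], errors="coerce")
    for i in df.index[(bp < 0) | (bp > 100)]:
        problems.append(f"row {i + 2}: bolting_pct outside [0, 100]: {df.loc[i, 'bolting_pct']!r}")
    if problems:
        raise ValidationError(path, problems)
    out = df[TRIAL_COLUMNS].copy()
    out["environment"] = out["location"].astype(str) + out["year"].astype(str)
    return out


def write_trials(df: pd.DataFrame, path) -> None:
    df[TRIAL_COLUMNS].to_csv(path, index=False)


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration (defaults mirror the study protocol)."""

    weather_path: str = "weather.csv"
    trials_path: str = "trials.csv"
    out_dir: str = "reports"
    sowing_dates: dict[str, dt.date] = dataclasses.field(default_factory=dict)
    end_month_day: tuple[int, int] = (6, 30)  # accumulation stops June 30
    hx: float = DEFAULT_HX
    devern_tmax: float = DEVERN_TMAX
    vern_window: tuple[float, float] = VERN_WINDOW
    no_bolting_sites: tuple[str, ...] = ("DEF",)
    theta_y: float = 50.0
    theta_s: float = 50.0
    pressure: float = 0.25
    goals: dict[str, str] = dataclasses.field(default_factory=lambda: dict(DEFAULT_GOALS))
    alpha_gei: float = 0.05  # GEI significance gate for the stability stages
    seed: int = 0

    def __post_init__(self) -> None:
        if self.devern_tmax <= self.vern_window[1]:
            raise ValueError("devernalization cutoff must exceed the window upper bound")
        if not 0 < self.pressure < 1:
            raise ValueError("selection pressure must be in (0, 1)")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["sowing_dates"] = {k: str(v) for k, v in self.sowing_dates.items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
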