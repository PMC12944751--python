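"""Synthetic weather, trial and bolting data with known ground truth.

The generator emulates the statistical features the pipeline consumes:

* autumn-to-summer daily weather following an annual sinusoid (cold winter
  delivering hours in the 0-13 °C vernalization window, warm spring days
  above the 23 °C devernalization cutoff) plus Gaussian noise;
* balanced RCBD multi-environment phenotypes Y = mu + E + B(E) + G + GE + e
  with controllable variance components and a low-rank bilinear GE
  interaction (the structure AMMI assumes);
* plot-level bolting percentages following the flat-then-linear response to
  vernalization intensity with binomial counting noise.

Effect vectors are drawn iid Gaussian, then centered and rescaled so their
df-adjusted empirical variance equals the configured sigma2 exactly
(variance control): expected ANOVA mean squares then hold per draw, so
recovery studies measure estimator behavior rather than generator noise.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .vernalization import DailyWeather

_DAYS_PER_YEAR = 365.25
#: day-of-year of the coldest day of the annual cycle (mid January)
_COLDEST_DOY = 15


@dataclasses.dataclass(frozen=True)
class WeatherParams:
    annual_mean: float = 18.0
    annual_amplitude: float = 12.0
    diurnal_range: float = 10.0
    noise_sd: float = 2.0
    start_date: dt.date = dt.date(2023, 10, 1)
    n_days: int = 270

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.diurnal_range <= 0:
            raise ValueError("diurnal_range must be > 0")


@dataclasses.dataclass(frozen=True)
class BoltingParams:
    """True thresholds (vernalizing hours) and slopes (% per hour) per genotype."""

    vt_true: tuple[float, ...]
    slope_true: tuple[float, ...]
    n_plants: int = 100

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.vt_true):
            raise ValueError("vt_true must be >= 0")
        if any(s < 0 for s in self.slope_true):
            raise ValueError("slope_true must be >= 0")
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_genotypes: int = 12
    n_environments: int = 6
    n_blocks: int = 4
    mu: float = 15.0
    sigma2_E: float = 4.0
    sigma2_G: float = 1.0
    sigma2_GE: float = 0.8
    sigma2_block: float = 0.5
    sigma2_res: float = 3.0
    gei_rank: int = 2
    #: exact double-centering of the GE matrix mimics a sum-to-zero
    #: (fixed-effect-style) interaction; the default keeps the random
    #: row/column shares an iid interaction carries, so the standard mixed
    #: model's expected mean squares hold and REML recovers every component
    center_gei: bool = False
    weather: WeatherParams = WeatherParams()
    bolting: BoltingParams | None = None

    def __post_init__(self) -> None:
        for name in ("sigma2_E", "sigma2_G", "sigma2_GE", "sigma2_block", "sigma2_res"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_genotypes < 2 or self.n_environments < 2 or self.n_blocks < 2:
            raise ValueError("need g >= 2, e >= 2, b >= 2")
        if not 1 <= self.gei_rank <= min(self.n_genotypes, self.n_environments) - 1:
            raise ValueError("gei_rank must be in [1, min(g, e) - 1]")

    @property
    def genotypes(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_genotypes)]

    @property
    def environments(self) -> list[str]:
        return [f"ENV{i + 1}" for i in range(self.n_environments)]


def _scaled_effects(rng: np.random.Generator, n: int, sigma2: float) -> np.ndarray:
    """iid N(0, sigma2) draws, centered and rescaled to exact empirical variance."""
    if sigma2 == 0 or n < 2:
        return np.zeros(n)
    v = rng.standard_normal(n)
    v -= v.mean()
    ss = float(np.sum(v**2))
    if ss == 0:
        return np.zeros(n)
    return v * np.sqrt(sigma2 * (n - 1) / ss)


def gen_weather(
    config: SyntheticConfig,
    site: str = "SITE",
    mean_offset: float = 0.0,
    seed_offset: int = 0,
) -> list[DailyWeather]:
    """Daily Tmin/Tmax series from an annual sinusoid plus Gaussian noise.

    The daily midpoint follows annual_mean - amplitude * cos(2 pi (doy -
    coldest_doy) / 365.25); Tmin/Tmax sit half the diurnal range below/above
    it.  ``mean_offset`` shifts the whole series (site/year climate);
    ``seed_offset`` decorrelates the noise of different site-years.
    """
    w = config.weather
    rng = np.random.default_rng(config.seed * 1000 + seed_offset + 17)
    out = []
    for i in range(w.n_days):
        date = w.start_date + dt.timedelta(days=i)
        doy = date.timetuple().tm_yday
        tmid = (
            w.annual_mean
            + mean_offset
            - w.annual_amplitude * np.cos(2 * np.pi * (doy - _COLDEST_DOY) / _DAYS_PER_YEAR)
        )
        tmid += rng.normal(0.0, w.noise_sd) if w.noise_sd > 0 else 0.0
        out.append(
            DailyWeather(
                date=date,
                tmin=float(tmid - w.diurnal_range / 2),
                tmax=float(tmid + w.diurnal_range / 2),
                site=site,
            )
        )
    return out


def gen_met_trials(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Balanced g x e x b phenotypes with known effects.

    GE interaction is a rank-``gei_rank`` bilinear product of Gaussian
    factors, double-centered and rescaled so SS / ((g-1)(e-1)) = sigma2_GE.
    Returns the long plot table and a truth record holding every simulated
    effect.
    """
    rng = np.random.default_rng(config.seed)
    g, e, b = config.n_genotypes, config.n_environments, config.n_blocks

    env_eff = _scaled_effects(rng, e, config.sigma2_E)
    gen_eff = _scaled_effects(rng, g, config.sigma2_G)
    blk_eff = _scaled_effects(rng, e * b, config.sigma2_block).reshape(e, b)

    if config.sigma2_GE > 0:
        M = rng.standard_normal((g, config.gei_rank)) @ rng.standard_normal(
            (config.gei_rank, e)
        )
        if config.center_gei:
            M = M - M.mean(axis=1, keepdims=True) - M.mean(axis=0, keepdims=True) + M.mean()
            target_ss = config.sigma2_GE * (g - 1) * (e - 1)
        else:
            # a Gaussian low-rank product is orthogonally invariant, so
            # fixing its total SS to g*e*sigma2 makes every ANOVA stratum
            # receive the same expected share an iid interaction would
            target_ss = config.sigma2_GE * g * e
        ss = float(np.sum(M**2))
        M = M * np.sqrt(target_ss / ss) if ss > 0 else M * 0
    else:
        M = np.zeros((g, e))

    resid = _scaled_effects(rng, g * e * b, config.sigma2_res).reshape(g, e, b)

    rows = []
    for j, gen in enumerate(config.genotypes):
        for i, env in enumerate(config.environments):
            for k in range(b):
                y = (
                    config.mu
                    + env_eff[i]
                    + blk_eff[i, k]
                    + gen_eff[j]
                    + M[j, i]
                    + resid[j, i, k]
                )
                rows.append((env, gen, f"B{k + 1}", y))
    df = pd.DataFrame(rows, columns=["environment", "genotype", "block", "value"])
    truth = {
        "mu": config.mu,
        "env_effects": pd.Series(env_eff, index=config.environments),
        "gen_effects": pd.Series(gen_eff, index=config.genotypes),
        "block_effects": blk_eff,
        "gei_matrix": pd.DataFrame(
            M, index=config.genotypes, columns=config.environments
        ),
    }
    return df, truth


def bolting_expected(x, vt: float, slope: float) -> np.ndarray:
    """Expected bolting %: clamp(slope * (x - vt), 0, 100)."""
    return np.clip(slope * (np.asarray(x, dtype=float) - vt), 0.0, 100.0)


def gen_bolting(
    config: SyntheticConfig,
    intensities: dict[str, float] | pd.Series,
) -> pd.DataFrame:
    """Plot-level bolting percentages for each genotype x environment x block.

    ``intensities`` maps environment to its cumulative vernalization
    intensity.  The realized percentage is a binomial draw on
    ``n_plants`` at the clamped flat-then-linear expectation.
    """
    if config.bolting is None:
        raise ValueError("config.bolting parameters are not set")
    bp = config.bolting
    if len(bp.vt_true) != config.n_genotypes or len(bp.slope_true) != config.n_genotypes:
        raise ValueError("vt_true/slope_true length must equal n_genotypes")
    intensities = pd.Series(intensities, dtype=float)
    if (intensities < 0).any():
        raise ValueError("intensities must be >= 0")
    rng = np.random.default_rng(config.seed + 9973)
    rows = []
    for j, gen in enumerate(config.genotypes):
        for env, x in intensities.items():
            p = float(bolting_expected(x, bp.vt_true[j], bp.slope_true[j])) / 100.0
            for k in range(config.n_blocks):
                y = 100.0 * rng.binomial(bp.n_plants, p) / bp.n_plants
                rows.append((str(env), gen, f"B{k + 1}", float(x), y))
    return pd.DataFrame(rows, columns=["environment", "genotype", "block", "x", "y"])
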