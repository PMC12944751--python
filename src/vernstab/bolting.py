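"""Biphasic (flat-then-linear) bolting response fits.

Bolting percentage of a biennial beet stays at zero until the cumulative
vernalization intensity x reaches the genotype's vernalization threshold
(VT) and then rises linearly.  The model fitted per genotype is

    f(x) = max(0, slope * (x - VT))

with slope >= 0.  VT is found by grid search and the slope by closed-form
least squares through the breakpoint; sensitivity is reported per 10
vernalizing hours, the field's conventional increment.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class BoltingObservation:
    genotype: str
    environment: str
    x: float  # vernalization intensity (vernalizing hours)
    y: float  # bolting percentage, 0-100

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError(f"vernalization intensity must be >= 0, got {self.x}")
        if not 0.0 <= self.y <= 100.0:
            raise ValueError(f"bolting percentage must be in [0, 100], got {self.y}")


@dataclasses.dataclass(frozen=True)
class BiphasicFit:
    genotype: str
    vt: float          # breakpoint, vernalizing hours
    slope: float       # % bolting per vernalizing hour
    sensitivity10: float  # % bolting per 10 vernalizing hours (= 10 * slope)
    sse: float
    n_obs: int
    converged: bool


def _sse_for_breakpoint(x: np.ndarray, y: np.ndarray, vt: float) -> tuple[float, float]:
    """Least-squares slope (clamped >= 0) and SSE for a candidate breakpoint."""
    dx = x - vt
    right = dx > 0
    denom = float(np.sum(dx[right] ** 2))
    slope = float(np.sum(dx[right] * y[right]) / denom) if denom > 0 else 0.0
    slope = max(slope, 0.0)
    pred = np.where(right, slope * dx, 0.0)
    return slope, float(np.sum((y - pred) ** 2))


def fit_biphasic(
    obs: Iterable[BoltingObservation] | pd.DataFrame,
    grid_step: float = 0.1,
) -> BiphasicFit:
    """Fit the flat-then-linear bolting model to one genotype's observations.

    VT is searched on a grid of resolution ``grid_step`` spanning the
    observed x range; ties in SSE are broken toward the largest VT (the most
    conservative threshold).  If every observation is zero the fit is the
    degenerate flat line (VT at the largest observed intensity, slope 0)
    flagged ``converged=False``.
    """
    if isinstance(obs, pd.DataFrame):
        genotype = str(obs["genotype"].iloc[0]) if "genotype" in obs else ""
        x = obs["x"].to_numpy(dtype=float)
        y = obs["y"].to_numpy(dtype=float)
    else:
        obs = list(obs)
        genotype = obs[0].genotype if obs else ""
        x = np.array([o.x for o in obs], dtype=float)
        y = np.array([o.y for o in obs], dtype=float)

    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("all x identical: breakpoint not identifiable")

    xmin, xmax = float(np.min(x)), float(np.max(x))
    if np.all(y == 0):
        return BiphasicFit(genotype, xmax, 0.0, 0.0, 0.0, len(x), converged=False)

    n_steps = int(np.floor((xmax - xmin) / grid_step + 1e-9))
    grid = xmin + grid_step * np.arange(n_steps + 1)
    if grid[-1] < xmax:  # always include the right edge
        grid = np.append(grid, xmax)

    best_vt, best_slope, best_sse = xmin, 0.0, np.inf
    for vt in grid:
        slope, sse = _sse_for_breakpoint(x, y, vt)
        # >= : ties broken toward the largest VT
        if sse <= best_sse + 1e-12:
            best_vt, best_slope, best_sse = float(vt), slope, sse
    converged = best_slope >= 0 and np.isfinite(best_sse)
    return BiphasicFit(
        genotype=genotype,
        vt=best_vt,
        slope=best_slope,
        sensitivity10=10.0 * best_slope,
        sse=best_sse,
        n_obs=len(x),
        converged=converged and best_slope > 0,
    )


def fit_all_genotypes(
    table: pd.DataFrame,
    grid_step: float = 0.1,
    exclude_sites: Sequence[str] = (),
) -> list[BiphasicFit]:
    """Fit the biphasic model per genotype from a long table.

    ``table`` needs columns genotype, environment, x, y.  Environments whose
    identifier starts with any prefix in ``exclude_sites`` are dropped before
    fitting (sites where bolting never occurs carry no threshold signal).
    """
    df = table.copy()
    if exclude_sites:
        mask = ~df["environment"].astype(str).str.startswith(tuple(exclude_sites))
        df = df[mask]
    fits = []
    for genotype, sub in df.groupby("genotype", sort=True):
        fits.append(fit_biphasic(sub.assign(genotype=str(genotype)), grid_step=grid_step))
    return fits


def rank_genotypes(fits: Iterable[BiphasicFit]) -> pd.DataFrame:
    """Genotypes ordered by descending VT with sensitivity attached.

    Ties in VT are broken by genotype identifier so the report is stable
    under permutation of the input.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    df = pd.DataFrame(
        {
            "genotype": [f.genotype for f in fits],
            "vt": [f.vt for f in fits],
            "slope": [f.slope for f in fits],
            "sensitivity10": [f.sensitivity10 for f in fits],
            "sse": [f.sse for f in fits],
            "n_obs": [f.n_obs for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    df = df.sort_values(["vt", "genotype"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)
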