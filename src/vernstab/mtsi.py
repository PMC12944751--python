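"""Factor analysis across traits and the multi-trait stability index (MTSI).

Genotypes are scored on the factors of the trait correlation matrix
(eigenvalue-greater-than-one retention, varimax rotation, regression-method
scores).  The MTSI of a genotype is its Euclidean distance, in factor-score
space, from an ideal genotype holding the best value of every trait;
genotypes are ranked ascending (smaller distance = closer to the ideal) and
the selected fraction yields per-trait selection differentials (SD%) and
gains (SG% = SD% x heritability).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors


@dataclasses.dataclass
class FactorModel:
    data: pd.DataFrame            # genotype x trait input matrix
    means: pd.Series
    sds: pd.Series
    eigenvalues: np.ndarray       # all p eigenvalues, descending
    loadings: pd.DataFrame        # trait x factor, varimax-rotated, signed
    variance_pct: np.ndarray      # per retained factor, % of total variance
    cumulative_pct: np.ndarray
    communality: pd.Series
    uniqueness: pd.Series
    scores: pd.DataFrame          # genotype x factor (regression method)
    weights: pd.DataFrame         # trait x factor score weights B = R^-1 L


@dataclasses.dataclass
class MTSIResult:
    mtsi: pd.Series               # per genotype, ascending is better
    ranking: pd.Index
    ideal_scores: pd.Series       # factor scores of the ideal genotype
    selected: list
    pressure: float


def factor_analysis(trait_matrix: pd.DataFrame) -> FactorModel:
    """Correlation-matrix factor analysis of a genotype x trait table.

    Retains factors with eigenvalue > 1 (at least one), rotates the loading
    matrix with varimax, and computes genotype scores by the regression
    method.  The sign of each factor is fixed so its largest-|loading| trait
    loads positively.
    """
    if trait_matrix.shape[1] < 3:
        raise ValueError("need at least 3 traits")
    X = trait_matrix.to_numpy(dtype=float)
    n, p = X.shape
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        const = list(trait_matrix.columns[sds == 0])
        raise ValueError(f"constant trait column(s): {const}")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    R = np.corrcoef(X, rowvar=False)
    if np.linalg.matrix_rank(R) < p:
        raise ValueError("singular trait correlation matrix")

    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    f = max(int(np.sum(eigvals > 1.0)), 1)
    if n < f + 1:
        raise ValueError(f"need at least {f + 1} genotypes for {f} factors")

    L = eigvecs[:, :f] * np.sqrt(eigvals[:f])
    if f > 1:
        L_rot, _ = rotate_factors(L, "varimax")
    else:
        L_rot = L.copy()
    for k in range(f):
        j = int(np.argmax(np.abs(L_rot[:, k])))
        if L_rot[j, k] < 0:
            L_rot[:, k] *= -1

    communality = np.sum(L_rot**2, axis=1)
    B = np.linalg.solve(R, L_rot)  # regression-method score weights
    scores = Z @ B

    factors = [f"FA{k + 1}" for k in range(f)]
    traits = trait_matrix.columns
    return FactorModel(
        data=trait_matrix.copy(),
        means=pd.Series(means, index=traits),
        sds=pd.Series(sds, index=traits),
        eigenvalues=eigvals,
        loadings=pd.DataFrame(L_rot, index=traits, columns=factors),
        variance_pct=100.0 * eigvals[:f] / p,
        cumulative_pct=np.cumsum(100.0 * eigvals[:f] / p),
        communality=pd.Series(communality, index=traits),
        uniqueness=pd.Series(1.0 - communality, index=traits),
        scores=pd.DataFrame(scores, index=trait_matrix.index, columns=factors),
        weights=pd.DataFrame(B, index=traits, columns=factors),
    )


def _ideal_trait_vector(model: FactorModel, goals: dict[str, str]) -> pd.Series:
    vals = {}
    for trait in model.data.columns:
        goal = goals.get(trait)
        if goal not in ("increase", "decrease"):
            raise ValueError(f"goal for trait {trait!r} must be 'increase' or 'decrease'")
        col = model.data[trait]
        vals[trait] = float(col.max() if goal == "increase" else col.min())
    return pd.Series(vals)[model.data.columns]


def mtsi(model: FactorModel, goals: dict[str, str], pressure: float = 0.25) -> MTSIResult:
    """Multi-trait stability index: distance to the ideal genotype.

    The ideal genotype takes the best observed value of every trait given
    its goal; its factor scores come from the same regression projection as
    the real genotypes.  MTSI_i = sqrt(sum_f (gamma_if - gamma*_f)^2).
    """
    if not 0 < pressure < 1:
        raise ValueError("selection pressure must be in (0, 1)")
    ideal = _ideal_trait_vector(model, goals)
    z_ideal = (ideal - model.means) / model.sds
    gamma_star = pd.Series(
        z_ideal.to_numpy() @ model.weights.to_numpy(), index=model.scores.columns
    )
    diffs = model.scores - gamma_star
    vals = np.sqrt((diffs**2).sum(axis=1))
    mtsi_series = pd.Series(vals, index=model.scores.index, name="MTSI")
    ranked = mtsi_series.sort_values(kind="mergesort")
    n_sel = int(round(pressure * len(ranked)))
    selected = list(ranked.index[:n_sel])
    return MTSIResult(
        mtsi=mtsi_series,
        ranking=ranked.index,
        ideal_scores=gamma_star,
        selected=selected,
        pressure=pressure,
    )


def selection_gain(
    result: MTSIResult,
    trait_means: pd.DataFrame,
    h2: dict[str, float] | pd.Series,
    goals: dict[str, str],
) -> pd.DataFrame:
    """Per-trait selection differential SD% and gain SG% for the selected set.

    SD% is the relative change of the selected-group mean against the grand
    mean on the original trait scale; SG% = SD% x h2.  A differential is
    favorable when its sign matches the trait's goal.
    """
    if not result.selected:
        raise ValueError("empty selection")
    h2 = pd.Series(h2)
    grand = trait_means.mean(axis=0)
    sel = trait_means.loc[result.selected].mean(axis=0)
    sd_pct = 100.0 * (sel - grand) / grand
    sg_pct = sd_pct * h2.reindex(sd_pct.index)
    goal_col = pd.Series({t: goals.get(t, "") for t in sd_pct.index})
    favorable = (sd_pct > 0) == (goal_col == "increase")
    return pd.DataFrame(
        {
            "goal": goal_col,
            "h2": h2.reindex(sd_pct.index),
            "SD_pct": sd_pct,
            "SG_pct": sg_pct,
            "favorable": favorable,
        }
    )


def factor_contributions(result: MTSIResult, model: FactorModel) -> pd.DataFrame:
    """Share of each factor in every genotype's squared MTSI.

    share_if = (gamma_if - gamma*_f)^2 / MTSI_i^2; rows sum to one.  A
    genotype exactly at the ideal (MTSI 0) gets uniform shares and a flag.
    """
    diffs2 = (model.scores - result.ideal_scores) ** 2
    total = diffs2.sum(axis=1)
    shares = diffs2.div(total.where(total > 0, np.nan), axis=0)
    f = model.scores.shape[1]
    degenerate = total == 0
    shares.loc[degenerate] = 1.0 / f
    shares["degenerate"] = degenerate
    return shares
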