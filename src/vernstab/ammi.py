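"""AMMI decomposition of genotype-by-environment interaction and the
WAASB / WAASBY stability-superiority indices.

AMMI subtracts additive genotype and environment means from the two-way
cell-mean table and decomposes the residual interaction by SVD; the k-th
multiplicative term explains EP_k = 100 * lambda_k^2 / sum(lambda^2) percent
of the interaction sum of squares and is tested with Gollob's approximate
F (df_k = g + e - 1 - 2k).  WAASB is the EP-weighted average of absolute
interaction principal-component (IPC) scores — computed here from the
decomposition of the shrunken BLUP interaction matrix — and WAASBY blends
rescaled mean performance with rescaled WAASB.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class AMMIDecomposition:
    interaction: pd.DataFrame          # double-centered g x e matrix
    singular_values: np.ndarray        # length P = min(g-1, e-1)
    genotype_scores: pd.DataFrame      # g x P, IPC scaling u * sqrt(lambda)
    environment_scores: pd.DataFrame   # e x P
    explained: np.ndarray              # EP_k, %
    table: pd.DataFrame                # per-component df, SS, MS, F, p, sig


def double_center(cell_means: pd.DataFrame) -> pd.DataFrame:
    """Interaction residuals: subtract row and column means, add grand mean."""
    m = cell_means.to_numpy(dtype=float)
    grand = m.mean()
    resid = m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + grand
    return pd.DataFrame(resid, index=cell_means.index, columns=cell_means.columns)


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ammi_decompose(
    cell_means: pd.DataFrame,
    ms_error: float,
    replicates: int,
    df_error: int | None = None,
) -> AMMIDecomposition:
    """AMMI analysis of a complete genotype x environment cell-mean table.

    ``ms_error`` is the plot-level residual mean square and ``replicates``
    the number of blocks; interaction sums of squares are reported on the
    plot-level scale (replicates * lambda_k^2) so component mean squares are
    directly comparable with the ANOVA residual.
    """
    if cell_means.isna().any().any():
        raise ValueError("cell-mean matrix has missing cells")
    g, e = cell_means.shape
    if g < 2 or e < 2:
        raise ValueError("need at least 2 genotypes and 2 environments")
    inter = double_center(cell_means)
    u, s, vt = np.linalg.svd(inter.to_numpy(), full_matrices=False)
    n_comp = min(g - 1, e - 1)
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]
    # deterministic sign: largest-|entry| genotype score positive per axis
    for k in range(n_comp):
        j = int(np.argmax(np.abs(u[:, k])))
        if u[j, k] < 0:
            u[:, k] *= -1
            vt[k] *= -1

    ss_total = float(np.sum(s**2))
    explained = 100.0 * s**2 / ss_total if ss_total > 0 else np.zeros(n_comp)

    rows = []
    for k in range(n_comp):
        df_k = g + e - 1 - 2 * (k + 1)
        ss_k = replicates * float(s[k] ** 2)
        ms_k = ss_k / df_k
        f_k = ms_k / ms_error if ms_error > 0 else np.nan
        if df_error is not None and np.isfinite(f_k):
            p_k = float(stats.f.sf(f_k, df_k, df_error))
        else:
            p_k = np.nan
        rows.append(
            (
                f"PC{k + 1}",
                df_k,
                ss_k,
                ms_k,
                f_k,
                p_k,
                _stars(p_k) if np.isfinite(p_k) else "",
                explained[k],
                float(np.sum(explained[: k + 1])),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["component", "df", "ss", "ms", "F", "p", "sig", "explained_pct", "cumulative_pct"],
    )

    scores_g = u * s  # IPC scaling: scores carry the singular values
    scores_e = vt.T * s
    cols = [f"IPC{k + 1}" for k in range(n_comp)]
    return AMMIDecomposition(
        interaction=inter,
        singular_values=s,
        genotype_scores=pd.DataFrame(scores_g, index=cell_means.index, columns=cols),
        environment_scores=pd.DataFrame(scores_e, index=cell_means.columns, columns=cols),
        explained=explained,
        table=table,
    )


def waasb(scores: pd.DataFrame, ep: np.ndarray) -> pd.Series:
    """Weighted average of absolute IPC scores.

    WAASB_i = sum_k |IPCA_ik| * EP_k / sum_k EP_k over all retained
    components.
    """
    ep = np.asarray(ep, dtype=float)
    if np.any(ep < 0):
        raise ValueError("explained proportions must be non-negative")
    total = ep.sum()
    if total == 0:
        raise ValueError("all explained proportions are zero")
    vals = (np.abs(scores.to_numpy(dtype=float)) * ep).sum(axis=1) / total
    return pd.Series(vals, index=scores.index, name="WAASB")


def _rescale(values: pd.Series, higher_is_better: bool) -> pd.Series:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        out = pd.Series(100.0, index=values.index)
        out.attrs["degenerate"] = True
        return out
    if higher_is_better:
        return 100.0 * (values - lo) / (hi - lo)
    return 100.0 * (hi - values) / (hi - lo)


def waasby(
    mean_yield: pd.Series,
    waasb_values: pd.Series,
    theta_y: float = 50.0,
    theta_s: float = 50.0,
) -> pd.DataFrame:
    """WAASBY superiority index: weighted blend of rescaled yield and WAASB.

    Yield is rescaled so the highest mean gets 100; WAASB so the lowest
    (most stable) gets 100; the blend uses weights theta_y / theta_s.
    """
    if theta_y + theta_s <= 0:
        raise ValueError("theta_y + theta_s must be positive")
    if len(mean_yield) < 2:
        raise ValueError("need at least 2 genotypes")
    r_g = _rescale(mean_yield, higher_is_better=True)
    r_w = _rescale(waasb_values.reindex(mean_yield.index), higher_is_better=False)
    score = (r_g * theta_y + r_w * theta_s) / (theta_y + theta_s)
    out = pd.DataFrame(
        {"rG": r_g, "rW": r_w, "WAASBY": score, "above_mean": score > score.mean()}
    )
    return out.sort_values("WAASBY", ascending=False)


def quadrant_classify(mean_yield: pd.Series, waasb_values: pd.Series) -> pd.Series:
    """Biplot quadrants I-IV from (yield vs its mean) x (WAASB vs its mean).

    I: low yield / high WAASB; II: high yield / high WAASB; III: low yield /
    low WAASB; IV: high yield / low WAASB (most desirable).  Points exactly
    on a mean line are assigned to the higher-yield / lower-WAASB side.
    """
    if len(mean_yield) < 1:
        raise ValueError("need at least one genotype")
    w = waasb_values.reindex(mean_yield.index)
    high_yield = mean_yield >= mean_yield.mean()
    low_waasb = w <= w.mean()
    labels = np.where(
        high_yield, np.where(low_waasb, "IV", "II"), np.where(low_waasb, "III", "I")
    )
    return pd.Series(labels, index=mean_yield.index, name="quadrant")
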