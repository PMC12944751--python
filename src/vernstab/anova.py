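"""Combined fixed-effects ANOVA for balanced multi-environment RCBD trials.

Model: Y_ijk = mu + E_i + B_k(E_i) + G_j + GE_ij + e_ijk.  Environments are
tested against the replication-within-environment stratum (blocks nested in
environments form the environment-level error in an RCBD MET); genotype and
interaction are tested against the plot residual.  Closed-form sums of
squares are used, which require a balanced table — unbalanced data are
rejected, not imputed.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

ENV, GEN, BLK = "environment", "genotype", "block"


class UnbalancedDesignError(ValueError):
    def __init__(self, missing_cells):
        self.missing_cells = list(missing_cells)
        shown = ", ".join(map(str, self.missing_cells[:8]))
        more = "" if len(self.missing_cells) <= 8 else f" (+{len(self.missing_cells) - 8} more)"
        super().__init__(f"design not balanced; missing/duplicated cells: {shown}{more}")


def _check_balance(df: pd.DataFrame) -> tuple[int, int, int]:
    envs = df[ENV].unique()
    gens = df[GEN].unique()
    blks = df[BLK].unique()
    counts = df.groupby([ENV, GEN, BLK], observed=True).size()
    bad = [
        cell
        for cell in itertools.product(envs, gens, blks)
        if counts.get(cell, 0) != 1
    ]
    bad += [idx for idx, c in counts.items() if c != 1]
    if bad:
        raise UnbalancedDesignError(sorted(set(map(tuple, bad))))
    return len(gens), len(envs), len(blks)


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def combined_anova(plots: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Combined ANOVA table for one trait over a balanced g x e x b design.

    Returns a DataFrame with rows Environment, Replication(Environment),
    Genotype, Genotype-environment, Residuals, Total and columns
    source, df, ss, ms, F, p, sig.
    """
    g, e, b = _check_balance(plots)
    y = plots[trait].to_numpy(dtype=float)
    grand = y.mean()
    n = len(y)

    m_env = plots.groupby(ENV, observed=True)[trait].mean()
    m_gen = plots.groupby(GEN, observed=True)[trait].mean()
    m_eb = plots.groupby([ENV, BLK], observed=True)[trait].mean()
    m_ge = plots.groupby([ENV, GEN], observed=True)[trait].mean()

    ss_total = float(np.sum((y - grand) ** 2))
    ss_env = g * b * float(np.sum((m_env - grand) ** 2))
    ss_blk = g * float(np.sum((m_eb - m_env.reindex(m_eb.index.get_level_values(0)).values) ** 2))
    ss_gen = e * b * float(np.sum((m_gen - grand) ** 2))
    inter = (
        m_ge
        - m_env.reindex(m_ge.index.get_level_values(0)).values
        - m_gen.reindex(m_ge.index.get_level_values(1)).values
        + grand
    )
    ss_ge = b * float(np.sum(inter**2))
    ss_res = ss_total - ss_env - ss_blk - ss_gen - ss_ge

    df_env, df_blk = e - 1, e * (b - 1)
    df_gen, df_ge = g - 1, (g - 1) * (e - 1)
    df_res = e * (b - 1) * (g - 1)
    assert df_env + df_blk + df_gen + df_ge + df_res == n - 1

    ms = {
        "Environment": ss_env / df_env,
        "Replication(Environment)": ss_blk / df_blk,
        "Genotype": ss_gen / df_gen,
        "Genotype-environment": ss_ge / df_ge,
        "Residuals": ss_res / df_res,
    }
    f_env = ms["Environment"] / ms["Replication(Environment)"]
    f_gen = ms["Genotype"] / ms["Residuals"]
    f_ge = ms["Genotype-environment"] / ms["Residuals"]
    p_env = stats.f.sf(f_env, df_env, df_blk)
    p_gen = stats.f.sf(f_gen, df_gen, df_res)
    p_ge = stats.f.sf(f_ge, df_ge, df_res)

    rows = [
        ("Environment", df_env, ss_env, ms["Environment"], f_env, p_env, _stars(p_env)),
        ("Replication(Environment)", df_blk, ss_blk, ms["Replication(Environment)"], np.nan, np.nan, ""),
        ("Genotype", df_gen, ss_gen, ms["Genotype"], f_gen, p_gen, _stars(p_gen)),
        ("Genotype-environment", df_ge, ss_ge, ms["Genotype-environment"], f_ge, p_ge, _stars(p_ge)),
        ("Residuals", df_res, ss_res, ms["Residuals"], np.nan, np.nan, ""),
        ("Total", n - 1, ss_total, np.nan, np.nan, np.nan, ""),
    ]
    return pd.DataFrame(rows, columns=["source", "df", "ss", "ms", "F", "p", "sig"])


def cell_residuals(plots: pd.DataFrame, trait: str) -> pd.Series:
    """Plot residuals after removing environment, block and GE cell means."""
    _check_balance(plots)
    m_eb = plots.groupby([ENV, BLK], observed=True)[trait].transform("mean")
    m_ge = plots.groupby([ENV, GEN], observed=True)[trait].transform("mean")
    m_env = plots.groupby(ENV, observed=True)[trait].transform("mean")
    return plots[trait] - m_eb - m_ge + m_env


def assumption_checks(plots: pd.DataFrame, trait: str) -> dict[str, float]:
    """Shapiro-Wilk p on residuals, Levene p on residuals across environments."""
    if plots[ENV].nunique() < 2:
        raise ValueError("need at least 2 environments for Levene's test")
    resid = cell_residuals(plots, trait)
    if len(resid) < 3:
        raise ValueError("need at least 3 residuals")
    shapiro_p = float(stats.shapiro(resid).pvalue)
    groups = [grp.to_numpy() for _, grp in resid.groupby(plots[ENV], observed=True)]
    levene_p = float(stats.levene(*groups, center="mean").pvalue)
    return {"shapiro_p": shapiro_p, "levene_p": levene_p}


def lsd_groups(
    cell_means: pd.Series,
    mse: float,
    df_error: int,
    r: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's LSD letter display for a set of equally replicated means.

    Means closer than LSD = t(1-alpha/2, df_error) * sqrt(2 mse / r) share a
    letter; letters are assigned greedily starting from the largest mean.
    """
    if mse <= 0:
        raise ValueError("mse must be positive")
    if r <= 0:
        raise ValueError("replication r must be positive")
    lsd = stats.t.ppf(1 - alpha / 2, df_error) * np.sqrt(2.0 * mse / r)
    means = cell_means.sort_values(ascending=False)
    names = list(means.index)
    # one candidate group per mean: everything within LSD below it; drop
    # groups nested in an earlier one.  Two means then share a letter iff
    # they differ by less than LSD (all-pairs consistency).
    groups: list[set] = []
    for i, name in enumerate(names):
        grp = {n for n in names[i:] if means[name] - means[n] < lsd}
        if not any(grp <= kept for kept in groups):
            groups.append(grp)
    labels = {name: "" for name in names}
    for letter_idx, grp in enumerate(groups):
        letter = chr(ord("a") + letter_idx)
        for n in names:
            if n in grp:
                labels[n] += letter
    out = pd.DataFrame({"mean": means, "group": [labels[n] for n in means.index]})
    out.attrs["lsd"] = float(lsd)
    return out
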