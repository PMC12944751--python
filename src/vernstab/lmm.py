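"""REML variance components, heritability and BLUPs for balanced MET data.

The working model is Y = mu + E + Rep(E) + G + GE + e with genotype (G) and
genotype-by-environment (GE) random.  For a balanced g x e x b table the
residual log-likelihood factors into independent strata — one chi-square
quadratic form per ANOVA line, with eigenvalue equal to that line's expected
mean square — so REML reduces to maximizing

    -1/2 * sum_s [ df_s log(lambda_s(sigma2)) + SS_s / lambda_s(sigma2) ]

over the non-negative variance components.  This is the exact REML optimum
for balanced data (the only kind accepted upstream) and is fast enough for
large simulation studies.  A fully-random variant (E and Rep(E) random too)
supplies the environment component for the variance-proportion report.

Derived summaries follow the genotype-mean basis:

    deltaP2 = sigma2_G + sigma2_GE/e + sigma2_res/(e*b)   (phenotypic var of a
                                                           genotype mean)
    hmg2    = sigma2_G / deltaP2                          (mean-basis heritability)
    accuracy = sqrt(hmg2)
    r2_ge   = sigma2_GE / (sigma2_G + sigma2_GE + sigma2_res)
    rge     = sigma2_G / (sigma2_G + sigma2_GE)           (genotypic correlation
                                                           across environments)
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .anova import BLK, ENV, GEN, combined_anova

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclasses.dataclass
class VarianceComponents:
    sigma2_E: float
    sigma2_G: float
    sigma2_GE: float
    sigma2_res: float
    proportions: dict[str, float]  # % of (E, G, GE), summing to 100
    deltaP2: float
    hmg2: float
    r2_ge: float
    accuracy: float
    rge: float


@dataclasses.dataclass
class BlupSet:
    genotype_blups: pd.Series
    ge_matrix: pd.DataFrame  # genotypes x environments
    loglik: float
    converged: bool


def _anova_ss(plots: pd.DataFrame, trait: str) -> dict:
    tab = combined_anova(plots, trait).set_index("source")
    return {
        "ss": tab["ss"].to_dict(),
        "df": tab["df"].to_dict(),
        "dims": (
            plots[GEN].nunique(),
            plots[ENV].nunique(),
            plots[BLK].nunique(),
        ),
    }


def _reml_strata(strata, n_comp, starts):
    """Maximize the stratum REML log-likelihood.

    ``strata`` is a list of (df, SS, coeff) where lambda = coeff @ sigma2.
    Returns (sigma2 estimates, maximized restricted log-likelihood, ok flag).
    """
    dfs = np.array([s[0] for s in strata], dtype=float)
    sss = np.array([s[1] for s in strata], dtype=float)
    coefs = np.array([s[2] for s in strata], dtype=float)

    def negll(v):
        lam = coefs @ v
        if np.any(lam <= 0):
            return 1e300  # finite penalty keeps numerical gradients defined
        return 0.5 * float(np.sum(dfs * np.log(lam) + sss / lam))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            negll,
            np.maximum(x0, 1e-8),
            method="L-BFGS-B",
            bounds=[(0.0, None)] * n_comp,
        )
        if best is None or res.fun < best.fun:
            best = res
    ll = -best.fun - 0.5 * float(np.sum(dfs)) * _LOG2PI
    return np.maximum(best.x, 0.0), ll, bool(np.isfinite(best.fun))


def _strata_full(plots, trait, drop=None):
    """Strata for the G/GE/res model (E, Rep(E) fixed).

    Component order: (sigma2_G, sigma2_GE, sigma2_res); ``drop`` removes a
    random term for likelihood-ratio tests.
    """
    a = _anova_ss(plots, trait)
    g, e, b = a["dims"]
    ss, df = a["ss"], a["df"]
    cG = [e * b, b, 1.0]
    cGE = [0.0, b, 1.0]
    cR = [0.0, 0.0, 1.0]
    if drop == "G":
        cG = [0.0, b, 1.0]
    elif drop == "GE":
        cG = [e * b, 0.0, 1.0]
        cGE = [0.0, 0.0, 1.0]
    strata = [
        (df["Genotype"], ss["Genotype"], cG),
        (df["Genotype-environment"], ss["Genotype-environment"], cGE),
        (df["Residuals"], ss["Residuals"], cR),
    ]
    # method-of-moments start from the ANOVA mean squares
    ms_g = ss["Genotype"] / df["Genotype"]
    ms_ge = ss["Genotype-environment"] / df["Genotype-environment"]
    ms_r = ss["Residuals"] / df["Residuals"]
    mom = np.array(
        [max((ms_g - ms_ge) / (e * b), 0.0), max((ms_ge - ms_r) / b, 0.0), ms_r]
    )
    starts = [mom, mom * 0.3 + 1e-3, mom * 3.0 + 1e-3]
    return strata, starts, (g, e, b)


def _fit_fully_random(plots, trait):
    """REML for the all-random variant; components (E, B, G, GE, res)."""
    a = _anova_ss(plots, trait)
    g, e, b = a["dims"]
    ss, df = a["ss"], a["df"]
    strata = [
        (df["Environment"], ss["Environment"], [g * b, g, 0.0, b, 1.0]),
        (df["Replication(Environment)"], ss["Replication(Environment)"], [0.0, g, 0.0, 0.0, 1.0]),
        (df["Genotype"], ss["Genotype"], [0.0, 0.0, e * b, b, 1.0]),
        (df["Genotype-environment"], ss["Genotype-environment"], [0.0, 0.0, 0.0, b, 1.0]),
        (df["Residuals"], ss["Residuals"], [0.0, 0.0, 0.0, 0.0, 1.0]),
    ]
    ms = {k: ss[k] / df[k] for k in ss if df.get(k)}
    ms_r = ms["Residuals"]
    mom = np.array(
        [
            max((ms["Environment"] - ms["Replication(Environment)"] - ms["Genotype-environment"] + ms_r) / (g * b), 0.0),
            max((ms["Replication(Environment)"] - ms_r) / g, 0.0),
            max((ms["Genotype"] - ms["Genotype-environment"]) / (e * b), 0.0),
            max((ms["Genotype-environment"] - ms_r) / b, 0.0),
            ms_r,
        ]
    )
    starts = [mom, mom * 0.3 + 1e-3, mom * 3.0 + 1e-3]
    v, ll, ok = _reml_strata(strata, 5, starts)
    return {"sigma2_E": v[0], "sigma2_B": v[1], "sigma2_G": v[2], "sigma2_GE": v[3], "sigma2_res": v[4], "loglik": ll, "ok": ok}


def _balanced_blups(plots, trait, s2g, s2ge, s2res, e, b):
    """Exact BLUPs on balanced data (environment and replication fixed).

    With every genotype seen in every environment/block the mixed-model
    equations decouple: the genotype BLUP is the hmg2-shrunken centered
    genotype mean, and the BLUP of the (double-centered) interaction is the
    cell-mean interaction residual shrunk by b*s2ge / (b*s2ge + s2res).
    """
    cell = plots.groupby([GEN, ENV], observed=True)[trait].mean().unstack()
    grand = float(plots[trait].mean())
    gmeans = cell.mean(axis=1)
    denom = s2g + s2ge / e + s2res / (e * b)
    shrink_g = s2g / denom if denom > 0 else 0.0
    u_g = shrink_g * (gmeans - grand)

    inter = cell.sub(cell.mean(axis=1), axis=0).sub(cell.mean(axis=0), axis=1) + grand
    c = b * s2ge / (b * s2ge + s2res) if (b * s2ge + s2res) > 0 else 0.0
    u_ge = c * inter
    return u_g.rename(None), u_ge


def fit_met_lmm(plots: pd.DataFrame, trait: str) -> tuple[VarianceComponents, BlupSet]:
    """REML fit of the MET mixed model for one trait, with BLUPs.

    Environment and replication are fixed for BLUP extraction; the
    environment variance reported in ``proportions`` comes from the
    fully-random variant of the model.
    """
    if plots[ENV].nunique() < 2 or plots[GEN].nunique() < 2:
        raise ValueError("need at least 2 environments and 2 genotypes")
    strata, starts, (g, e, b) = _strata_full(plots, trait)
    v, ll, ok = _reml_strata(strata, 3, starts)
    s2g, s2ge, s2res = map(float, v)

    full = _fit_fully_random(plots, trait)
    tot = full["sigma2_E"] + full["sigma2_G"] + full["sigma2_GE"]
    if tot > 0:
        props = {
            "E": 100.0 * full["sigma2_E"] / tot,
            "G": 100.0 * full["sigma2_G"] / tot,
            "GE": 100.0 * full["sigma2_GE"] / tot,
        }
    else:
        props = {"E": 0.0, "G": 0.0, "GE": 0.0}

    deltaP2 = s2g + s2ge / e + s2res / (e * b)
    hmg2 = s2g / deltaP2 if deltaP2 > 0 else 0.0
    denom = s2g + s2ge + s2res
    r2_ge = s2ge / denom if denom > 0 else 0.0
    rge = s2g / (s2g + s2ge) if (s2g + s2ge) > 0 else 0.0

    comps = VarianceComponents(
        sigma2_E=float(full["sigma2_E"]),
        sigma2_G=s2g,
        sigma2_GE=s2ge,
        sigma2_res=s2res,
        proportions=props,
        deltaP2=float(deltaP2),
        hmg2=float(hmg2),
        r2_ge=float(r2_ge),
        accuracy=float(np.sqrt(hmg2)),
        rge=float(rge),
    )
    u_g, u_ge = _balanced_blups(plots, trait, s2g, s2ge, s2res, e, b)
    blups = BlupSet(genotype_blups=u_g, ge_matrix=u_ge, loglik=float(ll), converged=ok)
    return comps, blups


def lrt_random_term(
    plots: pd.DataFrame,
    trait: str,
    term: str,
    boundary_correction: bool = False,
) -> tuple[float, float]:
    """Likelihood-ratio test for dropping one random term (``"G"`` or ``"GE"``).

    chi2 = 2 (ll_full - ll_reduced), one degree of freedom; the optional
    boundary correction halves the p-value (variance tested on its boundary).
    """
    if term not in ("G", "GE"):
        raise ValueError("term must be 'G' or 'GE'")
    strata, starts, _ = _strata_full(plots, trait)
    _, ll_full, _ = _reml_strata(strata, 3, starts)
    strata_r, starts_r, _ = _strata_full(plots, trait, drop=term)
    _, ll_red, _ = _reml_strata(strata_r, 3, starts_r)
    chi2 = 2.0 * (ll_full - ll_red)
    if chi2 < -1e-6:
        raise RuntimeError(
            f"reduced model out-likelihooded the full model (chi2={chi2:.3g}); refit needed"
        )
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=1))
    if boundary_correction:
        p = 0.5 * p if chi2 > 0 else 1.0
    return float(chi2), p


def ge_blup_matrix(blups: BlupSet) -> pd.DataFrame:
    """Genotype x environment matrix of predicted GE effects."""
    if not blups.converged:
        raise ValueError("BLUPs requested from a non-converged fit")
    return blups.ge_matrix.copy()
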