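"""End-to-end orchestration: synthetic study bundle and the full analysis.

``gen_study_bundle`` builds a complete study-shaped dataset — three sites
(two cool sites that score bolting, one hot site that never bolts) over two
cropping years, twelve genotypes, four blocks — with daily weather, six
plot-level traits and bolting counts, all with known ground truth.

``run_pipeline`` executes the whole chain on weather + trial tables:
vernalization intensities, biphasic bolting fits, quality traits, combined
ANOVA with assumption checks and LSD means, REML/BLUP variance components
with likelihood-ratio tests, AMMI + WAASB + WAASBY for the traits with
significant genotype-by-environment interaction, and the MTSI selection
stage.  Every table is written as CSV stamped with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ammi as ammi_mod
from . import anova as anova_mod
from . import bolting as bolting_mod
from . import lmm as lmm_mod
from . import quality
from .mtsi import factor_analysis, factor_contributions, mtsi as mtsi_index, selection_gain
from .io import MET_TRAITS, RunConfig, read_trials, read_weather, weather_to_days
from .synthetic import BoltingParams, SyntheticConfig, WeatherParams, gen_bolting, gen_met_trials, gen_weather
from .vernalization import cumulative_intensity

log = logging.getLogger("vernstab")

SITES = ("GND", "GCH", "DEF")
YEARS = ("2022-23", "2023-24")
#: site/year shifts of the annual mean temperature (°C): two cool bolting
#: sites with different winters and one hot site delivering almost no
#: vernalization (so it never bolts, like a warm lowland station)
SITE_OFFSET = {"GND": 2.7, "GCH": 4.75, "DEF": 9.0}
YEAR_OFFSET = {"2022-23": -0.4, "2023-24": 0.4}
#: sowing day-of-season per site (days after Sep 20)
SOWING = {
    ("GND", "2022-23"): dt.date(2022, 10, 12),
    ("DEF", "2022-23"): dt.date(2022, 9, 23),
    ("GCH", "2022-23"): dt.date(2022, 10, 14),
    ("GND", "2023-24"): dt.date(2023, 10, 12),
    ("DEF", "2023-24"): dt.date(2023, 9, 24),
    ("GCH", "2023-24"): dt.date(2023, 10, 11),
}

#: per-trait generator settings: grand mean and variance components
#: (sigma2_E, sigma2_G, sigma2_GE, sigma2_block, sigma2_res); yield traits
#: carry strong GEI, quality traits almost none, echoing typical MET findings
TRAIT_PARAMS = {
    "ry": dict(mu=90.0, sigma2_E=300.0, sigma2_G=25.0, sigma2_GE=20.0, sigma2_block=10.0, sigma2_res=60.0),
    "sc": dict(mu=17.0, sigma2_E=2.5, sigma2_G=0.8, sigma2_GE=0.02, sigma2_block=0.1, sigma2_res=0.7),
    "na": dict(mu=1.8, sigma2_E=0.2, sigma2_G=0.09, sigma2_GE=0.004, sigma2_block=0.01, sigma2_res=0.08),
    "k": dict(mu=4.5, sigma2_E=0.5, sigma2_G=0.25, sigma2_GE=0.02, sigma2_block=0.02, sigma2_res=0.2),
    "n": dict(mu=2.2, sigma2_E=0.4, sigma2_G=0.08, sigma2_GE=0.008, sigma2_block=0.02, sigma2_res=0.15),
}

#: true vernalization thresholds (vernalizing hours) and bolting slopes
#: (% per vernalizing hour) for the twelve genotypes — spread like the
#: thresholds and sensitivities a diverse hybrid panel shows
TRUE_VT = (107.0, 112.0, 116.0, 120.0, 123.0, 126.0, 128.0, 129.0, 131.0, 132.0, 133.0, 134.0)
TRUE_SLOPE = (1.0, 1.2, 1.4, 1.5, 1.7, 1.8, 1.9, 2.0, 2.1, 2.2, 2.3, 2.4)


def gen_study_bundle(seed: int = 0, n_plants: int = 100) -> dict:
    """Complete synthetic study: weather, trials, bolting, ground truth."""
    envs = [f"{site}{year}" for year in YEARS for site in SITES]
    weather_frames = []
    sowing, intensities = {}, {}
    base = SyntheticConfig(seed=seed)
    for i, (year, site) in enumerate([(y, s) for y in YEARS for s in SITES]):
        env = f"{site}{year}"
        sow = SOWING[(site, year)]
        end = dt.date(sow.year + 1, 6, 30)
        params = WeatherParams(start_date=sow, n_days=(end - sow).days + 1)
        cfg = dataclasses.replace(base, weather=params)
        days = gen_weather(
            cfg,
            site=env,
            mean_offset=SITE_OFFSET[site] + YEAR_OFFSET[year],
            seed_offset=i,
        )
        weather_frames.append(
            pd.DataFrame(
                {
                    "date": [d.date for d in days],
                    "tmin": [d.tmin for d in days],
                    "tmax": [d.tmax for d in days],
                    "site": env,
                }
            )
        )
        sowing[env] = sow
        intensities[env] = cumulative_intensity(days, sow, end)
    weather = pd.concat(weather_frames, ignore_index=True)

    truth = {"intensities": dict(intensities), "traits": {}}
    trait_tables = {}
    for t_idx, (trait, pars) in enumerate(TRAIT_PARAMS.items()):
        cfg = SyntheticConfig(seed=seed * 101 + t_idx + 1, **pars)
        df, tr = gen_met_trials(cfg)
        df["environment"] = df["environment"].map(dict(zip(cfg.environments, envs)))
        trait_tables[trait] = df.rename(columns={"value": trait})
        truth["traits"][trait] = tr
    merged = trait_tables["ry"][["environment", "genotype", "block", "ry"]]
    for trait in ("sc", "na", "k", "n"):
        merged = merged.merge(
            trait_tables[trait][["environment", "genotype", "block", trait]],
            on=["environment", "genotype", "block"],
        )
    for col in ("sc", "na", "k", "n", "ry"):
        merged[col] = merged[col].clip(lower=0.01)

    bolt_cfg = SyntheticConfig(
        seed=seed, bolting=BoltingParams(vt_true=TRUE_VT, slope_true=TRUE_SLOPE, n_plants=n_plants)
    )
    genmap = dict(zip(bolt_cfg.genotypes, sorted(merged["genotype"].unique())))
    bolt = gen_bolting(bolt_cfg, intensities)
    bolt["genotype"] = bolt["genotype"].map(genmap)
    bolt.loc[bolt["environment"].str.startswith("DEF"), "y"] = 0.0
    merged = merged.merge(
        bolt.rename(columns={"y": "bolting_pct"})[
            ["environment", "genotype", "block", "bolting_pct"]
        ],
        on=["environment", "genotype", "block"],
    )
    merged["location"] = merged["environment"].str[:3]
    merged["year"] = merged["environment"].str[3:]
    truth["bolting"] = {"vt_true": dict(zip(bolt_cfg.genotypes, TRUE_VT)),
                        "slope_true": dict(zip(bolt_cfg.genotypes, TRUE_SLOPE))}
    return {
        "weather": weather,
        "trials": merged,
        "sowing_dates": sowing,
        "intensities": intensities,
        "truth": truth,
    }


def _stamp(df: pd.DataFrame, cfg_hash: str, seed: int) -> pd.DataFrame:
    out = df.copy()
    out["config_hash"] = cfg_hash
    out["seed"] = seed
    return out


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis chain and write one CSV per report table."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    tables: dict[str, pd.DataFrame] = {}

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("read")
        weather = read_weather(config.weather_path)
        trials = read_trials(config.trials_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("read", exc) from exc

    try:
        stage("vernalize")
        intensities = {}
        for env in sorted(trials["environment"].unique()):
            days = weather_to_days(weather, env)
            if not days:
                raise ValueError(f"no weather for environment {env}")
            sow = config.sowing_dates.get(env, days[0].date)
            end = dt.date(
                sow.year + (1 if (config.end_month_day[0], config.end_month_day[1]) < (sow.month, sow.day) else 0),
                *config.end_month_day,
            )
            intensities[env] = cumulative_intensity(
                days, sow, end, hx=config.hx, devern_tmax=config.devern_tmax
            )
        tables["intensities"] = pd.DataFrame(
            sorted(intensities.items()), columns=["environment", "intensity"]
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("vernalize", exc) from exc

    try:
        stage("bolting-fit")
        obs = trials[["genotype", "environment", "bolting_pct"]].copy()
        obs["x"] = obs["environment"].map(intensities)
        obs = obs.rename(columns={"bolting_pct": "y"})
        fits = bolting_mod.fit_all_genotypes(
            obs[["genotype", "environment", "x", "y"]],
            exclude_sites=config.no_bolting_sites,
        )
        tables["fig1_biphasic"] = bolting_mod.rank_genotypes(fits)
    except Exception as exc:  # noqa: BLE001
        raise StageError("bolting-fit", exc) from exc

    try:
        stage("quality")
        trials = quality.derive_quality(trials)
    except Exception as exc:  # noqa: BLE001
        raise StageError("quality", exc) from exc

    try:
        stage("anova")
        anova_rows, check_rows, mean_rows = [], [], []
        gei_sig = {}
        ms_res, df_res = {}, {}
        for trait in MET_TRAITS:
            checks = anova_mod.assumption_checks(trials, trait)
            check_rows.append({"trait": trait, **checks})
            tab = anova_mod.combined_anova(trials, trait)
            tab.insert(0, "trait", trait)
            anova_rows.append(tab)
            idx = tab.set_index("source")
            gei_sig[trait] = float(idx.loc["Genotype-environment", "p"]) < config.alpha_gei
            ms_res[trait] = float(idx.loc["Residuals", "ms"])
            df_res[trait] = int(idx.loc["Residuals", "df"])
            r = trials.groupby(["environment"], observed=True)[trait].size().iloc[0]
            groups = anova_mod.lsd_groups(
                trials.groupby("environment", observed=True)[trait].mean(),
                ms_res[trait],
                df_res[trait],
                r=int(r),
            )
            groups = groups.reset_index().rename(columns={"index": "environment"})
            groups.insert(0, "trait", trait)
            mean_rows.append(groups)
        tables["table4_anova"] = pd.concat(anova_rows, ignore_index=True)
        tables["assumption_checks"] = pd.DataFrame(check_rows)
        tables["fig2_env_means"] = pd.concat(mean_rows, ignore_index=True)
    except Exception as exc:  # noqa: BLE001
        raise StageError("anova", exc) from exc

    try:
        stage("lmm")
        comp_rows, lrt_rows = [], []
        comps_by_trait, blups_by_trait = {}, {}
        for trait in MET_TRAITS:
            comps, blups = lmm_mod.fit_met_lmm(trials, trait)
            comps_by_trait[trait] = comps
            blups_by_trait[trait] = blups
            comp_rows.append(
                {
                    "trait": trait,
                    "sigma2_E": comps.sigma2_E,
                    "sigma2_G": comps.sigma2_G,
                    "sigma2_GE": comps.sigma2_GE,
                    "sigma2_res": comps.sigma2_res,
                    "prop_E": comps.proportions["E"],
                    "prop_G": comps.proportions["G"],
                    "prop_GE": comps.proportions["GE"],
                    "deltaP2": comps.deltaP2,
                    "hmg2": comps.hmg2,
                    "r2_ge": comps.r2_ge,
                    "accuracy": comps.accuracy,
                    "rge": comps.rge,
                }
            )
            for term in ("G", "GE"):
                chi2, p = lmm_mod.lrt_random_term(trials, trait, term)
                lrt_rows.append({"trait": trait, "term": term, "chi2": chi2, "p": p})
        tables["table4_components"] = pd.DataFrame(comp_rows)
        tables["table4_lrt"] = pd.DataFrame(lrt_rows)
    except Exception as exc:  # noqa: BLE001
        raise StageError("lmm", exc) from exc

    try:
        stage("stability")
        ammi_rows, waasb_rows, waasby_rows, quad_rows = [], [], [], []
        waasby_by_trait = {}
        n_blocks = trials["block"].nunique()
        for trait in MET_TRAITS:
            if not gei_sig[trait]:
                log.info("GEI not significant for %s; stability stage skipped", trait)
                continue
            cell = trials.groupby(["genotype", "environment"], observed=True)[trait].mean().unstack()
            dec = ammi_mod.ammi_decompose(
                cell, ms_res[trait], n_blocks, df_error=df_res[trait]
            )
            tab = dec.table.copy()
            tab.insert(0, "trait", trait)
            ammi_rows.append(tab)

            blup_dec = ammi_mod.ammi_decompose(
                lmm_mod.ge_blup_matrix(blups_by_trait[trait]),
                ms_res[trait],
                n_blocks,
                df_error=df_res[trait],
            )
            w = ammi_mod.waasb(blup_dec.genotype_scores, blup_dec.explained)
            gmeans = cell.mean(axis=1)
            wy = ammi_mod.waasby(gmeans, w, config.theta_y, config.theta_s)
            waasby_by_trait[trait] = wy
            quad = ammi_mod.quadrant_classify(gmeans, w)
            waasb_rows.append(
                pd.DataFrame({"trait": trait, "genotype": w.index, "mean": gmeans, "WAASB": w})
            )
            wy2 = wy.reset_index().rename(columns={"index": "genotype"})
            wy2.insert(0, "trait", trait)
            waasby_rows.append(wy2)
            quad_rows.append(
                pd.DataFrame({"trait": trait, "genotype": quad.index, "quadrant": quad})
            )
        if ammi_rows:
            tables["table5_ammi"] = pd.concat(ammi_rows, ignore_index=True)
            tables["fig4_waasb"] = pd.concat(waasb_rows, ignore_index=True)
            tables["fig5_waasby"] = pd.concat(waasby_rows, ignore_index=True)
            tables["fig4_quadrants"] = pd.concat(quad_rows, ignore_index=True)
    except Exception as exc:  # noqa: BLE001
        raise StageError("stability", exc) from exc

    try:
        stage("mtsi")
        mtsi_traits = ["ry", "sc", "na", "k", "n", "bolting_pct"]
        goals = {t: config.goals.get(t, "increase") for t in mtsi_traits}
        gmean = {
            t: trials.groupby("genotype", observed=True)[t].mean() for t in mtsi_traits
        }
        # bolting heritability from the bolting-scored environments only
        bolt_plots = trials[
            ~trials["location"].astype(str).str.startswith(tuple(config.no_bolting_sites))
        ]
        h2 = {}
        for t in mtsi_traits:
            if t == "bolting_pct":
                comps_b, _ = lmm_mod.fit_met_lmm(bolt_plots, t)
                h2[t] = comps_b.hmg2
            else:
                h2[t] = comps_by_trait[t].hmg2
        # input matrix: WAASBY where GEI was significant, rescaled
        # goal-oriented genotype means otherwise
        cols = {}
        for t in mtsi_traits:
            if t in waasby_by_trait:
                cols[t] = waasby_by_trait[t]["WAASBY"].reindex(gmean[t].index)
            else:
                cols[t] = ammi_mod._rescale(gmean[t], goals[t] == "increase")
        X = pd.DataFrame(cols)
        model = factor_analysis(X)
        # the matrix is already oriented (higher = better), so every column
        # is maximized when building the ideal genotype
        result = mtsi_index(model, {t: "increase" for t in mtsi_traits}, pressure=config.pressure)
        gains = selection_gain(
            result, pd.DataFrame(gmean), h2, goals
        )
        contrib = factor_contributions(result, model)

        fa = model.loadings.copy()
        fa["communality"] = model.communality
        fa["uniqueness"] = model.uniqueness
        fa = fa.reset_index().rename(columns={"index": "trait"})
        tables["table6_factors"] = fa
        eig = pd.DataFrame(
            {
                "factor": model.loadings.columns,
                "eigenvalue": model.eigenvalues[: model.loadings.shape[1]],
                "variance_pct": model.variance_pct,
                "cumulative_pct": model.cumulative_pct,
            }
        )
        tables["table6_eigen"] = eig
        gains2 = gains.reset_index().rename(columns={"index": "trait"})
        tables["table6_gains"] = gains2
        rank = pd.DataFrame(
            {
                "genotype": result.ranking,
                "MTSI": result.mtsi.reindex(result.ranking).to_numpy(),
                "selected": [g in result.selected for g in result.ranking],
            }
        )
        tables["fig6_mtsi"] = rank
        tables["fig6_contributions"] = contrib.reset_index().rename(columns={"index": "genotype"})
    except Exception as exc:  # noqa: BLE001
        raise StageError("mtsi", exc) from exc

    for name, df in tables.items():
        _stamp(df, cfg_hash, config.seed).to_csv(out_dir / f"{name}.csv", index=False)
    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "tables": sorted(tables),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tables
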