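"""End-to-end analysis orchestration.

Runs the whole two-environment quantitative-genetics analysis on a trait
table (measured or simulated): trait scaling and family filtering, the
grouped / pooled / constrained multivariate REML fits with their
likelihood-ratio tests, random-skewers and Flury-CPC matrix comparisons,
the phenotypic (individual-level) and population-level two-group path
models, phenotypic correlations and the nodule-number ANOVAs.  Every
stage's artefacts are written into the output directory and collected in
a report bundle; failures in one stage are logged and do not destroy the
results of earlier stages.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .covmatrix import CovMatrix
from .cpc import cpc_jump_up, cpc_likelihood_ratios
from .descriptive import nodule_anova, pearson_by_env, population_means
from .mixedmodel import (
    DEFAULT_TRAITS,
    MixedModelSpec,
    MultiTraitMixedModel,
    filter_families,
    lrt,
    scale_traits,
)
from .pathsem import GroupSample, PathModel, herbivory_nodulation_spec
from .simulate import (
    SimulationConfig,
    generate_experiment,
    read_trait_table,
    write_trait_table,
)
from .skewers import random_skewers_r, skewers_equality_test

__all__ = ["AnalysisConfig", "run_full_analysis", "REPORT_SECTIONS"]

logger = logging.getLogger("gmatools")

#: sections a complete report bundle contains
REPORT_SECTIONS = [
    "treatment_means",
    "correlations",
    "g_matrices",
    "lrt_grouping",
    "lrt_constraint",
    "skewers",
    "cpc",
    "sem_phenotypic",
    "population_means",
    "sem_population",
    "anova_individuals",
    "anova_population_means",
]


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run."""

    seed: int
    input_csv: str | Path | None = None
    sim_config: SimulationConfig | None = None
    output_dir: str | Path = "gmatools_out"
    trait_names: list[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    env_names: list[str] | None = None
    min_per_env: int = 2
    n_vectors: int = 1000
    n_null: int = 999
    n_randomizations: int = 999
    constraint: tuple[str, str] = ("nodules", "herbivory")

    def __post_init__(self) -> None:
        if self.input_csv is None and self.sim_config is None:
            raise ValueError("provide either input_csv or sim_config")
        if self.n_vectors < 1 or self.min_per_env < 0:
            raise ValueError("counts must be positive")
        if self.seed is None:
            raise ValueError("seed must be set explicitly")


def _matrix_block(M: CovMatrix) -> dict:
    return {
        "labels": M.labels,
        "values": M.values.tolist(),
        "n_effective": int(M.n_effective),
        "psd": bool(M.psd),
    }


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Execute every analysis stage and write the report bundle.

    Returns a dict with one entry per completed section plus ``errors``
    mapping failed stage names to their exception text.  Deterministic for
    a fixed seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    bundle: dict = {"errors": {}, "seed": config.seed, "version": __version__}
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(99,)))
    logger.info("gmatools %s, seed=%d", __version__, config.seed)

    def stage(name):
        def deco(fn):
            try:
                bundle[name] = fn()
                logger.info("stage %s: ok", name)
            except Exception as err:  # noqa: BLE001 - keep partial results
                bundle["errors"][name] = f"{type(err).__name__}: {err}"
                logger.error("stage %s failed: %s\n%s", name, err, traceback.format_exc())
            return fn

        return deco

    # ---- input -------------------------------------------------------
    if config.input_csv is not None:
        table = read_trait_table(config.input_csv)
    else:
        table = generate_experiment(config.sim_config)
        write_trait_table(table, out / "trait_table.csv")
    traits = config.trait_names
    envs = config.env_names or sorted(table["env"].unique())

    scaled, factors = scale_traits(table, traits)
    filtered = filter_families(scaled, config.min_per_env)
    write_trait_table(filtered, out / "trait_table_prepared.csv")
    bundle["scaling_factors"] = factors
    bundle["n_records"] = int(len(filtered))
    logger.info(
        "prepared: %d records, %d families retained, %d dropped",
        len(filtered),
        filtered.attrs.get("families_retained", -1),
        filtered.attrs.get("families_dropped", -1),
    )

    @stage("treatment_means")
    def _means():
        return {
            e: {t: float(table.loc[table["env"] == e, t].mean()) for t in traits}
            for e in envs
        }

    @stage("correlations")
    def _corr():
        res = pearson_by_env(filtered, traits)
        for e, mats in res.items():
            mats["r"].to_csv(out / f"pearson_r_{e}.csv")
        return {
            e: {k: v.to_dict() for k, v in mats.items()} for e, mats in res.items()
        }

    # ---- REML fits -----------------------------------------------------
    fits = {}

    @stage("g_matrices")
    def _fit_g():
        fits["grouped"] = MultiTraitMixedModel(
            filtered, MixedModelSpec(grouping="by_env"), traits
        ).fit()
        res = fits["grouped"]
        block = {}
        for e in envs:
            res.G_by_env[e].to_csv(out / f"G_{e}.csv")
            res.R_by_env[e].to_csv(out / f"R_{e}.csv")
            block[e] = {
                "G": _matrix_block(res.G_by_env[e]),
                "R": _matrix_block(res.R_by_env[e]),
            }
        block["reml_loglik"] = res.reml_loglik
        block["n_cov_params"] = res.n_cov_params
        block["converged"] = res.converged
        return block

    @stage("lrt_grouping")
    def _lrt_group():
        fits["pooled"] = MultiTraitMixedModel(
            filtered, MixedModelSpec(grouping="none"), traits
        ).fit()
        r = lrt(fits["grouped"], fits["pooled"])
        return {"chi2": r.statistic, "df": r.df, "p": r.p_chi2}

    @stage("lrt_constraint")
    def _lrt_con():
        fits["constrained"] = MultiTraitMixedModel(
            filtered, MixedModelSpec(grouping="by_env", constraint=config.constraint), traits
        ).fit()
        r = lrt(fits["grouped"], fits["constrained"])
        return {
            "constraint": list(config.constraint),
            "chi2": r.statistic,
            "df": r.df,
            "p": r.p_chi2,
        }

    # ---- matrix comparisons --------------------------------------------
    @stage("skewers")
    def _skewers():
        sub = np.random.default_rng(rng.integers(2**31))
        if config.n_null < 1:
            logger.warning("n_null = 0: reporting skewers statistic without a p-value")
            G1 = fits["grouped"].G_by_env[envs[0]]
            G2 = fits["grouped"].G_by_env[envs[1]]
            r = random_skewers_r(G1, G2, config.n_vectors, sub)
            return {"r_mean": r, "p": None, "n_null": 0}
        res = skewers_equality_test(
            filtered,
            n_vectors=config.n_vectors,
            n_null=config.n_null,
            rng=sub,
            trait_names=traits,
        )
        logger.info(
            "skewers: %d null replicates, %d failed", res.n_null, res.n_failed
        )
        return {
            "r_mean": res.r_mean,
            "p": res.p_value,
            "n_null": res.n_null,
            "n_vectors": res.n_vectors,
        }

    @stage("cpc")
    def _cpc():
        sub = np.random.default_rng(rng.integers(2**31))
        if config.n_randomizations < 1:
            logger.warning("n_randomizations = 0: reporting CPC LRs without p-values")
            from .mixedmodel import family_mean_covariance

            S1 = family_mean_covariance(filtered, envs[0], traits)
            S2 = family_mean_covariance(filtered, envs[1], traits)
            lrs = cpc_likelihood_ratios(S1, S2)
            return {
                lv: {"lr": v[0], "p": None} for lv, v in lrs.items()
            }
        res = cpc_jump_up(
            None, None, filtered, config.n_randomizations, sub, trait_names=traits
        )
        return {
            r.level: {
                "lr": r.lr_statistic,
                "df_chi2": r.df_chi2,
                "p_randomization": r.p_randomization,
                "n_randomizations": r.n_randomizations,
            }
            for r in res
        }

    # ---- structural equation models ------------------------------------
    sem_spec = herbivory_nodulation_spec()

    @stage("sem_phenotypic")
    def _sem_pheno():
        samples = []
        for e in envs:
            sub = filtered.loc[filtered["env"] == e, list(sem_spec.variables)]
            S = np.cov(sub.to_numpy(dtype=float), rowvar=False)
            samples.append(
                GroupSample(e, CovMatrix(list(sem_spec.variables), S, len(sub)), len(sub))
            )
        fit = PathModel(samples, sem_spec).fit()
        (out / "sem_phenotypic.txt").write_text(fit.summary() + "\n")
        cfi, rmsea = fit.fit_indices()
        return {
            "chi2": fit.chi2,
            "df": fit.df,
            "p": fit.p_value,
            "cfi": cfi,
            "rmsea": rmsea,
            "standardized": fit.standardized,
            "r_squared": fit.r_squared,
            "total_effect_herbivory_on_nodules": {
                g: float(T.loc["nodules", "herbivory"])
                for g, T in fit.total_effects().items()
            },
            "critical_ratios": fit.critical_ratios().to_dict(orient="records"),
        }

    @stage("population_means")
    def _pop_means():
        pm = population_means(filtered, fits["grouped"])
        pm.to_csv(out / "population_lsmeans.csv", index=False)
        return pm.to_dict(orient="records")

    @stage("sem_population")
    def _sem_pop():
        pm = population_means(filtered, fits["grouped"])
        samples = []
        for e in envs:
            sub = pm.loc[pm["env"] == e, list(sem_spec.variables)]
            S = np.cov(sub.to_numpy(dtype=float), rowvar=False)
            samples.append(
                GroupSample(e, CovMatrix(list(sem_spec.variables), S, len(sub)), len(sub))
            )
        fit = PathModel(samples, sem_spec).fit()
        cfi, rmsea = fit.fit_indices()
        txt = fit.summary() + (
            "\nNote: with so few populations per group the ML chi-square "
            "rests on a very small sample; interpret with caution.\n"
        )
        (out / "sem_population.txt").write_text(txt)
        return {
            "chi2": fit.chi2,
            "df": fit.df,
            "p": fit.p_value,
            "cfi": cfi,
            "rmsea": rmsea,
            "n_per_group": int(len(pm) // len(envs)),
            "standardized": fit.standardized,
            "total_effect_herbivory_on_nodules": {
                g: float(T.loc["nodules", "herbivory"])
                for g, T in fit.total_effects().items()
            },
            "small_sample_caveat": True,
        }

    @stage("anova_individuals")
    def _anova_ind():
        tab = nodule_anova(filtered, "individuals")
        tab.to_csv(out / "anova_individuals.csv")
        return tab.to_dict(orient="index")

    @stage("anova_population_means")
    def _anova_pop():
        tab = nodule_anova(filtered, "population_means")
        tab.to_csv(out / "anova_population_means.csv")
        return tab.to_dict(orient="index")

    with open(out / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=str)
    logger.removeHandler(handler)
    handler.close()
    return bundle
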