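"""Family-structured multi-trait data simulation in two environments.

The generator emulates a field quantitative-genetics experiment: inbred
maternal families nested within natural populations, planted into blocks
that each receive one of two whole-plot light treatments (sun / shade),
scored for four traits -- nodule number, herbivory (proportion of damaged
leaves), root biomass and shoot biomass.  Every plant's trait vector is

    mu_env + population effect + family-within-population effect
           + block effect + residual,

with the population effect drawn once per population (from ``P_pop``), the
family effect drawn once per family x environment (from ``G_env``; the
simulated analogue of broad-sense genetic variation, optionally shared
across environments), diagonal block effects, and a within-plant residual
from ``R_env``.  Survival is independent Bernoulli per plant with an
environment-specific probability; herbivory is generated directly on the
proportion scale and clipped to [0, 1], the remaining traits are floored
at zero.

Randomness is organised as one master seed with deterministic sub-streams
per population / family / block / plant, so enlarging the design never
perturbs draws already made for existing units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .covmatrix import CovMatrix
from . import datasets

__all__ = [
    "SimulationConfig",
    "generate_experiment",
    "true_family_mean_covariance",
    "study_config",
    "write_trait_table",
    "read_trait_table",
]

#: canonical column order of the trait-table CSV dialect
TABLE_COLUMNS = [
    "plant_id",
    "population",
    "family",
    "block",
    "env",
    "nodules",
    "herbivory",
    "root",
    "shoot",
]

_PSD_TOL = 1e-8


def _check_psd(name: str, m: np.ndarray, k: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (k, k):
        raise ValueError(f"{name} must be {k}x{k}, got {m.shape}")
    if np.abs(m - m.T).max() > 1e-8 * max(1.0, np.abs(m).max()):
        raise ValueError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(m)
    if w.min() < -_PSD_TOL * max(1.0, w.max()):
        raise ValueError(f"{name} is not positive semi-definite (min eig {w.min():.3g})")
    return 0.5 * (m + m.T)


def _psd_factor(m: np.ndarray) -> np.ndarray:
    """A factor L with L L' = m, valid for singular PSD matrices."""
    w, v = np.linalg.eigh(m)
    return v * np.sqrt(np.clip(w, 0.0, None))


@dataclass
class SimulationConfig:
    """Design and genetic architecture of a simulated experiment.

    Covariances are supplied in the trait's original measurement units.
    ``shared_family_effects=True`` maps a single standard-normal draw per
    family through each environment's G factor, giving per-environment
    marginal covariance ``G_env`` with perfect cross-environment
    correlation; the default draws independently per environment, matching
    a model that estimates separate per-environment G with no
    cross-environment covariance.
    """

    n_populations: int
    families_per_population: int
    replicates_per_family_per_env: int
    trait_names: list[str]
    env_names: list[str]
    mu_env: dict[str, np.ndarray]
    G_env: dict[str, np.ndarray]
    R_env: dict[str, np.ndarray]
    P_pop: np.ndarray
    n_blocks_per_env: int
    sigma_block: np.ndarray
    survival_prob_env: dict[str, float]
    seed: int
    shared_family_effects: bool = False

    def __post_init__(self) -> None:
        k = len(self.trait_names)
        if k != 4:
            raise ValueError(f"exactly 4 trait names required, got {k}")
        if len(self.env_names) != 2:
            raise ValueError(f"exactly 2 environment names required, got {len(self.env_names)}")
        for cnt_name in (
            "n_populations",
            "families_per_population",
            "replicates_per_family_per_env",
            "n_blocks_per_env",
        ):
            if getattr(self, cnt_name) < 1:
                raise ValueError(f"{cnt_name} must be >= 1")
        for e in self.env_names:
            for d in (self.mu_env, self.G_env, self.R_env, self.survival_prob_env):
                if e not in d:
                    raise ValueError(f"missing environment {e!r} in config mapping")
        self.mu_env = {e: np.asarray(self.mu_env[e], dtype=float) for e in self.env_names}
        for e in self.env_names:
            if self.mu_env[e].shape != (k,):
                raise ValueError(f"mu_env[{e!r}] must have length {k}")
        self.G_env = {e: _check_psd(f"G_env[{e!r}]", self.G_env[e], k) for e in self.env_names}
        self.R_env = {e: _check_psd(f"R_env[{e!r}]", self.R_env[e], k) for e in self.env_names}
        self.P_pop = _check_psd("P_pop", self.P_pop, k)
        self.sigma_block = np.asarray(self.sigma_block, dtype=float) * np.ones(k)
        if (self.sigma_block < 0).any():
            raise ValueError("sigma_block must be non-negative")
        for e, p in self.survival_prob_env.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(f"survival_prob_env[{e!r}] must be in (0, 1], got {p}")

    # -- serialisation -------------------------------------------------

    def to_yaml(self, path) -> None:
        def _l(a):
            return np.asarray(a).tolist()

        doc = {
            "n_populations": self.n_populations,
            "families_per_population": self.families_per_population,
            "replicates_per_family_per_env": self.replicates_per_family_per_env,
            "trait_names": list(self.trait_names),
            "env_names": list(self.env_names),
            "mu_env": {e: _l(v) for e, v in self.mu_env.items()},
            "G_env": {e: _l(v) for e, v in self.G_env.items()},
            "R_env": {e: _l(v) for e, v in self.R_env.items()},
            "P_pop": _l(self.P_pop),
            "n_blocks_per_env": self.n_blocks_per_env,
            "sigma_block": _l(self.sigma_block),
            "survival_prob_env": {e: float(p) for e, p in self.survival_prob_env.items()},
            "seed": self.seed,
            "shared_family_effects": self.shared_family_effects,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for key in ("mu_env", "G_env", "R_env"):
            doc[key] = {e: np.asarray(v, dtype=float) for e, v in doc[key].items()}
        doc["P_pop"] = np.asarray(doc["P_pop"], dtype=float)
        doc["sigma_block"] = np.asarray(doc["sigma_block"], dtype=float)
        return cls(**doc)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def generate_experiment(
    config: SimulationConfig, return_effects: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Simulate one experiment and return the surviving plants.

    Returns a trait table (one row per surviving plant) whose ``attrs``
    carry the per-trait clipping fractions (``clipped_fraction``, computed
    over surviving records) and the planted/surviving counts.  With
    ``return_effects=True`` additionally returns the un-thinned latent
    effects (population effects and per family x environment effects) for
    parameter-recovery oracles.
    """
    cfg = config
    k = len(cfg.trait_names)
    lower = np.array([0.0] * k)
    upper = np.array([np.inf, 1.0, np.inf, np.inf])  # trait 2 is a proportion

    Lp = _psd_factor(cfg.P_pop)
    Lg = {e: _psd_factor(cfg.G_env[e]) for e in cfg.env_names}
    Lr = {e: _psd_factor(cfg.R_env[e]) for e in cfg.env_names}

    for e in cfg.env_names:
        expected = cfg.replicates_per_family_per_env * cfg.survival_prob_env[e]
        if expected < 1.0:
            warnings.warn(
                f"expected surviving replication in {e!r} is {expected:.2f} "
                "plants per family (< 1); downstream family filtering will be severe",
                stacklevel=2,
            )

    pop_effects: dict[str, np.ndarray] = {}
    fam_effects: dict[tuple[str, str], np.ndarray] = {}

    rows = []
    values = []
    n_planted = 0
    for p in range(cfg.n_populations):
        pop = f"pop{p + 1:02d}"
        pop_effects[pop] = Lp @ _stream(cfg.seed, 1, p).standard_normal(k)
        for f in range(cfg.families_per_population):
            fam = f"{pop}-fam{f + 1:02d}"
            if cfg.shared_family_effects:
                z = _stream(cfg.seed, 2, p, f).standard_normal(k)
                for e in cfg.env_names:
                    fam_effects[(fam, e)] = Lg[e] @ z
            else:
                for ei, e in enumerate(cfg.env_names):
                    fam_effects[(fam, e)] = Lg[e] @ _stream(
                        cfg.seed, 2, p, f, ei
                    ).standard_normal(k)

    block_eff = {
        (e, b): cfg.sigma_block * _stream(cfg.seed, 3, ei, b).standard_normal(k)
        for ei, e in enumerate(cfg.env_names)
        for b in range(cfg.n_blocks_per_env)
    }

    for p in range(cfg.n_populations):
        pop = f"pop{p + 1:02d}"
        for f in range(cfg.families_per_population):
            fam = f"{pop}-fam{f + 1:02d}"
            for ei, e in enumerate(cfg.env_names):
                for rep in range(cfg.replicates_per_family_per_env):
                    n_planted += 1
                    rng = _stream(cfg.seed, 4, p, f, ei, rep)
                    b = int(rng.integers(cfg.n_blocks_per_env))
                    resid = Lr[e] @ rng.standard_normal(k)
                    alive = rng.uniform() < cfg.survival_prob_env[e]
                    if not alive:
                        continue
                    y = (
                        cfg.mu_env[e]
                        + pop_effects[pop]
                        + fam_effects[(fam, e)]
                        + block_eff[(e, b)]
                        + resid
                    )
                    rows.append(
                        (
                            f"{fam}-{e}-r{rep + 1:02d}",
                            pop,
                            fam,
                            f"{e}-blk{b + 1:02d}",
                            e,
                        )
                    )
                    values.append(y)

    vals = np.array(values) if values else np.empty((0, k))
    clipped = ((vals < lower) | (vals > upper)).mean(axis=0) if len(vals) else np.zeros(k)
    vals = np.clip(vals, lower, upper)

    table = pd.DataFrame(rows, columns=TABLE_COLUMNS[:5])
    for j, t in enumerate(cfg.trait_names):
        table[t] = vals[:, j] if len(vals) else np.array([])
    table.attrs["clipped_fraction"] = dict(zip(cfg.trait_names, clipped.tolist()))
    table.attrs["n_planted"] = n_planted
    table.attrs["n_survived"] = len(table)

    if return_effects:
        return table, {"population": pop_effects, "family": fam_effects}
    return table


def true_family_mean_covariance(config: SimulationConfig, env: str) -> CovMatrix:
    """The generator's family-effect covariance for one environment.

    This is the estimand of the REML G matrices and the oracle for
    parameter-recovery checks.
    """
    if env not in config.env_names:
        raise KeyError(f"unknown environment {env!r}; expected one of {config.env_names}")
    n_fam = config.n_populations * config.families_per_population
    return CovMatrix(list(config.trait_names), config.G_env[env].copy(), n_effective=n_fam)


# -- trait-table I/O ----------------------------------------------------


def write_trait_table(table: pd.DataFrame, path) -> None:
    table.loc[:, TABLE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_trait_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table is missing columns {missing}")
    return table


# -- study-like default configuration -----------------------------------


def _bend_psd(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    return v @ np.diag(np.clip(w, 0.0, None)) @ v.T


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration emulating the two-light-environment field study.

    Eight source populations, 7 inbred families per population (~55
    families), 15 replicate plants per family in each treatment spread over
    15 blocks per treatment (30 plots in all), and low field survival
    (26% sun, 30% shade; ~27-28% overall).  Trait means are the observed
    treatment means; the family-level covariance matrices are the published
    mean-scaled G estimates projected to the nearest PSD matrix and
    rescaled to original units; residual and among-population covariances
    encode the study's signature pattern -- negative phenotypic
    herbivory-size correlations within environments alongside positive
    family- and population-level herbivory-nodulation covariance.
    """
    traits = list(datasets.TRAITS)
    envs = list(datasets.ENVS)
    mu = {
        "sun": np.array([2.5, 0.45, 0.16, 1.32]),
        "shade": np.array([12.7, 0.29, 0.23, 2.0]),
    }
    grand = 0.5 * (mu["sun"] + mu["shade"])
    scale = np.outer(grand, grand)

    G_scaled = {e: _bend_psd(m.values) for e, m in datasets.study_family_matrices().items()}
    G = {e: G_scaled[e] * scale for e in envs}

    # residual correlation pattern: sizes and nodulation positively related,
    # herbivory negatively related to all three
    C = np.array(
        [
            [1.00, -0.45, 0.45, 0.35],
            [-0.45, 1.00, -0.30, -0.35],
            [0.45, -0.30, 1.00, 0.60],
            [0.35, -0.35, 0.60, 1.00],
        ]
    )
    sd_scaled = np.array([1.0, 0.45, 0.55, 0.55])  # residual SD relative to trait mean
    R = {e: C * np.outer(sd_scaled * mu[e], sd_scaled * mu[e]) for e in envs}

    P_scaled = np.array(
        [
            [0.30, 0.04, 0.05, 0.05],
            [0.04, 0.03, 0.00, 0.00],
            [0.05, 0.00, 0.04, 0.03],
            [0.05, 0.00, 0.03, 0.04],
        ]
    )
    P = P_scaled * scale

    cfg = dict(
        n_populations=8,
        families_per_population=7,
        replicates_per_family_per_env=15,
        trait_names=traits,
        env_names=envs,
        mu_env=mu,
        G_env=G,
        R_env=R,
        P_pop=P,
        n_blocks_per_env=15,
        sigma_block=0.15 * grand,
        survival_prob_env={"sun": 0.26, "shade": 0.30},
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def scaled_architecture_config(
    seed: int = 0,
    n_populations: int = 5,
    families_per_population: int = 55,
    replicates_per_family_per_env: int = 5,
    survival: float = 0.9,
    equal_G: bool = False,
    **overrides,
) -> SimulationConfig:
    """A stripped design carrying the study's mean-scaled genetic architecture.

    Family-level covariance equals the published mean-scaled G matrices
    (PSD-projected), with no population or block variance and trait means
    placed far from the clipping bounds, so Monte-Carlo studies of the
    estimators (parameter recovery, test calibration) see the genetic
    architecture undistorted by truncation.  ``equal_G=True`` gives both
    environments the shade matrix -- the matrix-equality null condition.
    """
    traits = list(datasets.TRAITS)
    envs = list(datasets.ENVS)
    G_scaled = {e: _bend_psd(m.values) for e, m in datasets.study_family_matrices().items()}
    if equal_G:
        G_scaled = {e: G_scaled["shade"] for e in envs}
    C = np.array(
        [
            [1.00, -0.20, 0.45, 0.35],
            [-0.20, 1.00, -0.25, -0.30],
            [0.45, -0.25, 1.00, 0.60],
            [0.35, -0.30, 0.60, 1.00],
        ]
    )
    s = np.array([0.3, 0.1, 0.3, 0.3])
    mu = {
        "sun": np.array([5.0, 0.5, 5.0, 5.0]),
        "shade": np.array([5.5, 0.45, 5.5, 5.5]),
    }
    cfg = dict(
        n_populations=n_populations,
        families_per_population=families_per_population,
        replicates_per_family_per_env=replicates_per_family_per_env,
        trait_names=traits,
        env_names=envs,
        mu_env=mu,
        G_env=G_scaled,
        R_env={e: C * np.outer(s, s) for e in envs},
        P_pop=np.zeros((4, 4)),
        n_blocks_per_env=1,
        sigma_block=np.zeros(4),
        survival_prob_env={e: survival for e in envs},
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)
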