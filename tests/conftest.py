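import numpy as np
import pandas as pd
import pytest

from gmatools.mixedmodel import filter_families, scale_traits
from gmatools.simulate import generate_experiment, study_config


@pytest.fixture(scope="session")
def small_config():
    """A fast fully-surviving design for unit tests."""
    return study_config(
        seed=3,
        n_populations=3,
        families_per_population=4,
        replicates_per_family_per_env=4,
        n_blocks_per_env=3,
        survival_prob_env={"sun": 1.0, "shade": 1.0},
    )


@pytest.fixture(scope="session")
def small_table(small_config):
    table = generate_experiment(small_config)
    table, _ = scale_traits(table)
    return filter_families(table)


@pytest.fixture(scope="session")
def study_table():
    """A study-emulating table (mortality, blocks, populations), prepared."""
    table = generate_experiment(study_config(seed=7))
    table, _ = scale_traits(table)
    return filter_families(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_single_trait_balanced(
    n_families: int = 30,
    n_reps: int = 6,
    fam_sd: float = 0.7,
    resid_sd: float = 1.0,
    seed: int = 42,
) -> pd.DataFrame:
    """Balanced one-way family design with a single trait."""
    rng = np.random.default_rng(seed)
    fam = np.repeat([f"f{i:02d}" for i in range(n_families)], n_reps)
    u = np.repeat(rng.normal(0.0, fam_sd, n_families), n_reps)
    y = 2.0 + u + rng.normal(0.0, resid_sd, n_families * n_reps)
    return pd.DataFrame(
        {
            "plant_id": [f"p{i}" for i in range(len(y))],
            "population": "pop1",
            "family": fam,
            "block": "b1",
            "env": "sun",
            "y": y,
        }
    )
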