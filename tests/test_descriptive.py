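import numpy as np
import pandas as pd
import pytest

from gmatools.descriptive import nodule_anova, pearson_by_env, population_means
from gmatools.mixedmodel import MixedModelSpec, MultiTraitMixedModel

TRAITS = ["nodules", "herbivory", "root", "shoot"]


def table_from_arrays(env, **cols):
    n = len(env)
    base = {
        "plant_id": [f"p{i}" for i in range(n)],
        "population": cols.pop("population", ["pop1"] * n),
        "family": cols.pop("family", ["f1"] * n),
        "block": cols.pop("block", ["b1"] * n),
        "env": env,
    }
    for t in TRAITS:
        base[t] = cols.get(t, np.ones(n))
    return pd.DataFrame(base)


class TestPearson:
    def test_exact_linear_relation_gives_unit_correlation(self, rng):
        x = rng.normal(0, 1, 50)
        t = table_from_arrays(["sun"] * 50, nodules=2 * x, root=x)
        res = pearson_by_env(t, ["nodules", "root"])["sun"]
        assert res["r"].loc["nodules", "root"] == pytest.approx(1.0)
        assert res["n"].loc["nodules", "root"] == 50

    def test_independent_traits_near_zero(self, rng):
        n = 4000
        t = table_from_arrays(
            ["sun"] * n,
            nodules=rng.normal(size=n),
            herbivory=rng.normal(size=n),
            root=rng.normal(size=n),
            shoot=rng.normal(size=n),
        )
        res = pearson_by_env(t)["sun"]
        off = res["r"].to_numpy()[np.triu_indices(4, 1)]
        assert np.abs(off).max() < 3.0 / np.sqrt(n)

    def test_constant_trait_reported_as_undefined(self, rng):
        t = table_from_arrays(
            ["sun"] * 10, nodules=rng.normal(size=10), root=np.full(10, 7.0)
        )
        res = pearson_by_env(t, ["nodules", "root"])["sun"]
        assert np.isnan(res["r"].loc["nodules", "root"])

    def test_negative_herbivory_size_pattern_in_study_simulation(self, study_table):
        """Within both light environments herbivory correlates negatively
        with nodulation and biomass while the size traits intercorrelate
        positively."""
        res = pearson_by_env(study_table)
        for e in ("sun", "shade"):
            r = res[e]["r"]
            assert r.loc["herbivory", "nodules"] < 0
            assert r.loc["herbivory", "root"] < 0
            assert r.loc["herbivory", "shoot"] < 0
            assert r.loc["root", "shoot"] > 0
            assert r.loc["nodules", "root"] > 0


class TestNoduleAnova:
    def test_zero_response_gives_zero_f(self, rng):
        n = 60
        t = table_from_arrays(
            ["sun", "shade"] * (n // 2),
            nodules=np.zeros(n),
            herbivory=rng.uniform(0, 1, n),
            root=rng.normal(1, 0.2, n),
            shoot=rng.normal(2, 0.3, n),
        )
        res = nodule_anova(t)
        assert (res["F"].fillna(0.0) == 0.0).all()

    def test_f_equals_squared_t_for_single_covariate(self, rng):
        """With a single informative covariate, the sequential F equals the
        square of the simple-regression t statistic."""
        import statsmodels.formula.api as smf

        n = 80
        x = rng.normal(0, 1, n)
        y = 1.5 * x + rng.normal(0, 1, n)
        t = table_from_arrays(
            ["sun"] * n,  # single environment: treatment terms are aliased
            nodules=y,
            herbivory=x,
            root=np.zeros(n),
            shoot=np.zeros(n),
        )
        res = nodule_anova(t)
        simple = smf.ols("y ~ x", data=pd.DataFrame({"x": x, "y": y})).fit()
        tval = simple.tvalues["x"]
        assert res.loc["herbivory", "F"] == pytest.approx(tval**2, rel=1e-6)
        assert "light_treatment" in res.attrs["aliased_terms"]

    def test_population_means_denominator_df_is_eight(self, study_table):
        res = nodule_anova(study_table, unit="population_means")
        assert res.attrs["df_resid"] == 8
        assert (res["df"] == 1).all()
        assert res.index[0] == "light_treatment"

    def test_printed_term_order(self, study_table):
        res = nodule_anova(study_table)
        assert list(res.index) == [
            "light_treatment",
            "herbivory",
            "root",
            "shoot",
            "light_treatment:herbivory",
            "light_treatment:root",
            "light_treatment:shoot",
        ]

    def test_unknown_unit_rejected(self, study_table):
        with pytest.raises(ValueError, match="unit"):
            nodule_anova(study_table, unit="families")


class TestPopulationMeans:
    def test_balanced_no_block_lsmeans_equal_raw_cell_means(self, rng):
        rows = []
        for pop in ("pop1", "pop2"):
            for env in ("sun", "shade"):
                for fam in ("a", "b", "c"):
                    for rep in range(3):
                        rows.append((pop, env, f"{pop}-{fam}", f"{env}-b1"))
        df = pd.DataFrame(rows, columns=["population", "env", "family", "block"])
        df["plant_id"] = [f"p{i}" for i in range(len(df))]
        for t in TRAITS:
            df[t] = rng.normal(1.0, 0.2, len(df))
        fit = MultiTraitMixedModel(df, MixedModelSpec()).fit()
        pm = population_means(df, fit).set_index(["population", "env"])
        raw = df.groupby(["population", "env"])[TRAITS].mean()
        for key in raw.index:
            np.testing.assert_allclose(
                pm.loc[key, TRAITS].to_numpy(dtype=float),
                raw.loc[key].to_numpy(),
                atol=1e-6,
            )

    def test_unbalanced_block_adjustment_opposes_imbalance(self, rng):
        """pop1 over-samples an inflated block; its lsmean drops below the
        raw mean while pop2 (under-sampled there) moves up."""
        rows = []
        # block b2 adds +1 to every trait; pop1 has 12 plants in b2, 3 in b1;
        # pop2 the reverse
        for pop, in_b2, in_b1 in (("pop1", 12, 3), ("pop2", 3, 12)):
            for fam in ("x", "y", "z"):
                for env in ("sun", "shade"):
                    nb2 = in_b2 // 3
                    nb1 = in_b1 // 3
                    for i in range(nb2):
                        rows.append((pop, env, f"{pop}-{fam}", f"{env}-b2", 1.0))
                    for i in range(nb1):
                        rows.append((pop, env, f"{pop}-{fam}", f"{env}-b1", 0.0))
        df = pd.DataFrame(
            rows, columns=["population", "env", "family", "block", "bump"]
        )
        df["plant_id"] = [f"p{i}" for i in range(len(df))]
        for t in TRAITS:
            df[t] = 1.0 + df["bump"] + rng.normal(0, 0.05, len(df))
        df = df.drop(columns="bump")
        fit = MultiTraitMixedModel(df, MixedModelSpec()).fit()
        pm = population_means(df, fit).set_index(["population", "env"])
        raw = df.groupby(["population", "env"])[TRAITS].mean()
        for env in ("sun", "shade"):
            assert pm.loc[("pop1", env), "nodules"] < raw.loc[("pop1", env), "nodules"]
            assert pm.loc[("pop2", env), "nodules"] > raw.loc[("pop2", env), "nodules"]

    def test_population_mismatch_rejected(self, small_table):
        fit = MultiTraitMixedModel(small_table, MixedModelSpec()).fit()
        with pytest.raises(ValueError, match="populations do not match"):
            population_means(small_table[small_table["population"] != "pop01"], fit)

    def test_sixteen_rows_for_eight_populations(self, study_table):
        fit = MultiTraitMixedModel(study_table, MixedModelSpec()).fit()
        pm = population_means(study_table, fit)
        assert len(pm) == study_table["population"].nunique() * 2
        assert set(TRAITS) <= set(pm.columns)
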