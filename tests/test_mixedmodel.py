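import numpy as np
import pandas as pd
import pytest

from gmatools.mixedmodel import (
    MixedModelSpec,
    MultiTraitMixedModel,
    filter_families,
    fit_multitrait_reml,
    lrt,
    scale_traits,
)
from gmatools.simulate import generate_experiment, scaled_architecture_config, study_config

from conftest import make_single_trait_balanced


class TestSpecValidation:
    def test_constraint_requires_grouping(self):
        with pytest.raises(ValueError, match="requires grouping"):
            MixedModelSpec(grouping="none", constraint=("nodules", "herbivory"))

    def test_unknown_grouping(self):
        with pytest.raises(ValueError, match="grouping"):
            MixedModelSpec(grouping="by_block")


class TestAnalyticGradient:
    @pytest.mark.parametrize(
        "spec",
        [
            MixedModelSpec(grouping="by_env"),
            MixedModelSpec(grouping="none"),
            MixedModelSpec(grouping="by_env", constraint=("nodules", "herbivory")),
            MixedModelSpec(grouping="by_env", family_structure="psd"),
        ],
        ids=["by_env", "pooled", "constrained", "psd"],
    )
    def test_gradient_matches_finite_differences(self, small_table, spec):
        m = MultiTraitMixedModel(small_table, spec)
        theta = m._start()
        # evaluate at the start and at a perturbed (still admissible) point
        rng = np.random.default_rng(0)
        for point in (theta, theta + 0.02 * rng.standard_normal(len(theta))):
            _, g = m._neg2_restricted(point)
            if m._last_penalty > 0:
                continue  # the floored region trades gradient exactness for continuity
            eps = 1e-6
            for i in range(0, len(point), 3):  # subsample parameters for speed
                tp, tm = point.copy(), point.copy()
                tp[i] += eps
                tm[i] -= eps
                fd = (
                    m._neg2_restricted(tp, want_grad=False)[0]
                    - m._neg2_restricted(tm, want_grad=False)[0]
                ) / (2 * eps)
                assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestSingleTraitOracle:
    def test_balanced_reml_equals_anova_moment_estimator(self):
        """Balanced one-way design: REML G and R equal the closed-form
        (MS_family - MS_error)/k and MS_error moment estimators."""
        nfam, nrep = 30, 6
        t = make_single_trait_balanced(nfam, nrep)
        res = fit_multitrait_reml(
            t, MixedModelSpec(grouping="none"), trait_names=["y"], fixed="env_only"
        )
        fam_means = t.groupby("family")["y"].mean()
        ms_fam = nrep * fam_means.var(ddof=1)
        within = t["y"] - t.groupby("family")["y"].transform("mean")
        ms_err = (within**2).sum() / (nfam * (nrep - 1))
        moment = (ms_fam - ms_err) / nrep
        assert res.G_by_env["sun"].values[0, 0] == pytest.approx(moment, rel=1e-6)
        assert res.R_by_env["sun"].values[0, 0] == pytest.approx(ms_err, rel=1e-6)


class TestStatsmodelsCrossCheck:
    def test_single_trait_reml_matches_mixedlm(self):
        """Independent route: statsmodels MixedLM on the same random-intercept
        model must reproduce the REML log-likelihood and both variance
        components."""
        smf = pytest.importorskip("statsmodels.formula.api")
        t = make_single_trait_balanced(25, 5, seed=9)
        res = fit_multitrait_reml(
            t, MixedModelSpec(grouping="none"), trait_names=["y"], fixed="env_only"
        )
        md = smf.mixedlm("y ~ 1", t, groups=t["family"]).fit(reml=True)
        assert res.reml_loglik == pytest.approx(md.llf, abs=1e-6)
        assert res.G_by_env["sun"].values[0, 0] == pytest.approx(
            md.cov_re.iloc[0, 0], rel=1e-4
        )
        assert res.R_by_env["sun"].values[0, 0] == pytest.approx(md.scale, rel=1e-4)


class TestBoundaryAndStructure:
    def test_zero_family_variance_estimated_near_boundary(self):
        cfg = scaled_architecture_config(
            seed=8,
            n_populations=2,
            families_per_population=20,
            G_env={
                "sun": np.zeros((4, 4)),
                "shade": np.zeros((4, 4)),
            },
            survival=1.0,
        )
        table = generate_experiment(cfg)
        res = MultiTraitMixedModel(table, MixedModelSpec(), fixed="env_only").fit()
        for e in ("sun", "shade"):
            diag = np.diag(res.G_by_env[e].values)
            # residual variances are ~0.01-0.09; family variances should be tiny
            assert np.abs(diag).max() < 0.02

    def test_psd_mode_returns_psd_family_matrices(self, small_table):
        res = MultiTraitMixedModel(
            small_table, MixedModelSpec(family_structure="psd")
        ).fit()
        for e, m in res.G_by_env.items():
            assert np.linalg.eigvalsh(m.values).min() >= -1e-10

    def test_residual_matrices_are_pd(self, small_table):
        res = MultiTraitMixedModel(small_table, MixedModelSpec()).fit()
        for m in res.R_by_env.values():
            assert np.linalg.eigvalsh(m.values).min() > 0


class TestParameterCounts:
    def test_grouped_vs_pooled_differ_by_twenty(self, small_table):
        grouped = MultiTraitMixedModel(small_table, MixedModelSpec(grouping="by_env"))
        pooled = MultiTraitMixedModel(small_table, MixedModelSpec(grouping="none"))
        assert grouped.n_cov_params == 40
        assert pooled.n_cov_params == 20
        assert grouped.n_cov_params - pooled.n_cov_params == 20

    def test_constraint_removes_one_parameter(self, small_table):
        con = MultiTraitMixedModel(
            small_table, MixedModelSpec(constraint=("nodules", "herbivory"))
        )
        assert con.n_cov_params == 39

    def test_constraint_is_honoured_in_estimates(self, small_table):
        res = MultiTraitMixedModel(
            small_table, MixedModelSpec(constraint=("nodules", "herbivory"))
        ).fit()
        assert res.G_by_env["sun"].values[0, 1] == pytest.approx(
            res.G_by_env["shade"].values[0, 1], abs=1e-12
        )


class TestLRT:
    @pytest.fixture(scope="class")
    def fits(self, small_table):
        full = MultiTraitMixedModel(small_table, MixedModelSpec()).fit()
        red = MultiTraitMixedModel(small_table, MixedModelSpec(grouping="none")).fit()
        con = MultiTraitMixedModel(
            small_table, MixedModelSpec(constraint=("nodules", "herbivory"))
        ).fit()
        return full, red, con

    def test_full_model_likelihood_dominates_nested(self, fits):
        full, red, con = fits
        assert full.reml_loglik >= red.reml_loglik - 1e-6
        assert full.reml_loglik >= con.reml_loglik - 1e-6

    def test_df_bookkeeping(self, fits):
        full, red, con = fits
        assert lrt(full, red).df == 20
        assert lrt(full, con).df == 1

    def test_statistic_nonnegative_and_chi2_p(self, fits):
        full, red, _ = fits
        r = lrt(full, red)
        assert r.statistic >= 0
        assert 0 <= r.p_chi2 <= 1

    def test_same_model_twice_errors(self, fits):
        full, _, _ = fits
        with pytest.raises(ValueError, match="fewer covariance parameters"):
            lrt(full, full)

    def test_different_data_errors(self, fits, study_table):
        full, _, _ = fits
        other = MultiTraitMixedModel(study_table, MixedModelSpec(grouping="none")).fit()
        with pytest.raises(ValueError, match="different data"):
            lrt(full, other)

    def test_statistic_invariant_to_common_rescaling(self, small_table):
        traits = ["nodules", "herbivory", "root", "shoot"]
        doubled = small_table.copy()
        doubled[traits] = doubled[traits] * 2.0
        stat = lambda t: lrt(  # noqa: E731
            MultiTraitMixedModel(t, MixedModelSpec()).fit(),
            MultiTraitMixedModel(t, MixedModelSpec(grouping="none")).fit(),
        ).statistic
        s1, s2 = stat(small_table), stat(doubled)
        assert s1 == pytest.approx(s2, rel=1e-3, abs=1e-3)


class TestFittedModelShape:
    def test_results_fields(self, small_table):
        res = MultiTraitMixedModel(small_table, MixedModelSpec()).fit()
        assert res.n_obs == 4 * len(small_table)
        assert set(res.G_by_env) == {"sun", "shade"}
        assert np.isfinite(res.reml_loglik)
        assert res.converged
        assert len(res.fixed_effects) == res.model.p_fixed
        text = res.summary()
        assert "REML log-likelihood" in text and "G[sun]" in text

    def test_aliased_columns_dropped_with_warning(self, small_table):
        t = small_table.copy()
        # a population label that coincides with environment aliases the
        # population dummy with the environment dummy
        t["population"] = t["env"]
        with pytest.warns(UserWarning, match="aliased"):
            MultiTraitMixedModel(t, MixedModelSpec())
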