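import numpy as np
import pytest

from gmatools.covmatrix import CovMatrix
from gmatools.pathsem import (
    GroupSample,
    PathModel,
    PathModelSpec,
    fit_indices,
    fit_multigroup,
    herbivory_nodulation_spec,
    implied_covariance,
    parse_model,
    simulate_group,
    total_effects,
)

TRUE = {
    "herbivory->root": -0.5,
    "herbivory->shoot": -0.7,
    "herbivory->nodules": 0.1,
    "root->nodules": 1.2,
    "shoot->nodules": 0.5,
    "herbivory~~herbivory": 1.0,
    "root~~root": 0.8,
    "shoot~~shoot": 0.9,
    "nodules~~nodules": 0.7,
    "root~~shoot": 0.4,
}


class TestSpecAndParser:
    def test_parse_study_topology(self):
        spec = herbivory_nodulation_spec()
        assert spec.variables == ("herbivory", "root", "shoot", "nodules")
        assert spec.exogenous == ("herbivory",)
        assert ("root", "nodules") in spec.directed_edges
        assert ("root", "shoot") in spec.error_covariances
        assert "root~~shoot" in spec.cross_group_equal

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            parse_model("a -> b\nb -> c\nc -> a")

    def test_unknown_constraint_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            parse_model("a -> b\nequal_across_groups: b->a")

    def test_unparseable_line(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_model("a => b")


class TestImpliedCovariance:
    def test_zero_coefficients_give_error_structure(self):
        spec = parse_model("x -> y")
        vals = {"x->y": 0.0, "x~~x": 2.0, "y~~y": 3.0}
        np.testing.assert_allclose(
            implied_covariance(vals, spec).values, np.diag([2.0, 3.0])
        )

    def test_single_edge_algebra(self):
        spec = parse_model("x -> y")
        b, v, e = 0.7, 2.0, 0.5
        sigma = implied_covariance({"x->y": b, "x~~x": v, "y~~y": e}, spec).values
        assert sigma[0, 1] == pytest.approx(b * v)
        assert sigma[1, 1] == pytest.approx(b**2 * v + e)

    def test_monte_carlo_simulation_oracle(self):
        """Brute force: the covariance of data simulated from the structural
        equations converges to the implied covariance."""
        spec = herbivory_nodulation_spec()
        sigma = implied_covariance(TRUE, spec).values
        data = simulate_group(TRUE, spec, 150_000, rng=0)
        emp = np.cov(data.to_numpy(), rowvar=False)
        assert np.abs(emp - sigma).max() < 0.03


class TestFitting:
    def exact_samples(self, n=600):
        sigma = implied_covariance(TRUE, herbivory_nodulation_spec())
        return [GroupSample("sun", sigma, n), GroupSample("shade", sigma, n)]

    def test_exact_fit_recovers_parameters_with_zero_chi2(self):
        spec = herbivory_nodulation_spec()
        fit = fit_multigroup(self.exact_samples(), spec)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 1
        cfi, rmsea = fit.fit_indices()
        assert cfi == 1.0 and rmsea == 0.0
        for k, v in TRUE.items():
            assert fit.estimates["sun"][k] == pytest.approx(v, abs=1e-5)

    def test_two_group_df_is_one_for_study_topology(self):
        fit = fit_multigroup(self.exact_samples(), herbivory_nodulation_spec())
        # 2 x 10 moments - 19 free parameters (one cross-group equality)
        assert fit.df == 1

    def test_saturated_single_group_df_zero_chi2_zero(self, rng):
        spec = parse_model("x -> y\nx -> z\ny -> z")
        A = rng.standard_normal((3, 3))
        S = CovMatrix(["x", "y", "z"], A @ A.T + np.eye(3))
        fit = fit_multigroup([GroupSample("g", S, 100)], spec)
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        cfi, rmsea = fit.fit_indices()
        assert cfi == 1.0 and rmsea is None

    def test_chi2_invariant_to_common_rescaling(self, rng):
        spec = herbivory_nodulation_spec()
        d1 = simulate_group(TRUE, spec, 500, rng=1)
        d2 = simulate_group(TRUE, spec, 500, rng=2)
        def fits(scale):
            samples = [
                GroupSample(
                    g,
                    CovMatrix(
                        list(spec.variables),
                        np.cov(d.to_numpy() * scale, rowvar=False),
                        500,
                    ),
                    500,
                )
                for g, d in (("sun", d1), ("shade", d2))
            ]
            return fit_multigroup(samples, spec).chi2
        assert fits(1.0) == pytest.approx(fits(3.0), rel=1e-5, abs=1e-6)

    def test_releasing_constraint_drops_chi2_and_df_by_one(self):
        spec = herbivory_nodulation_spec()
        free_spec = PathModelSpec(
            spec.variables, spec.directed_edges, spec.error_covariances, frozenset()
        )
        d1 = simulate_group(TRUE, spec, 400, rng=3)
        t2 = dict(TRUE, **{"root~~shoot": 0.2})
        d2 = simulate_group(t2, spec, 400, rng=4)
        samples = [
            GroupSample(
                g,
                CovMatrix(list(spec.variables), np.cov(d.to_numpy(), rowvar=False), 400),
                400,
            )
            for g, d in (("sun", d1), ("shade", d2))
        ]
        con = fit_multigroup(samples, spec)
        free = fit_multigroup(samples, free_spec)
        assert con.df == free.df + 1
        assert free.chi2 <= con.chi2 + 1e-8
        lrt_stat = con.chi2 - free.chi2
        assert lrt_stat > 0.0

    def test_nonpd_sample_covariance_rejected(self):
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            GroupSample("g", CovMatrix(["x", "y"], bad), 50)

    def test_sample_size_validation(self):
        with pytest.raises(ValueError, match="too small"):
            GroupSample("g", CovMatrix(["x", "y"], np.eye(2)), 2)


class TestEffectsAndIndices:
    def test_chain_total_effect_is_product(self):
        spec = parse_model("x -> m\nm -> y")
        vals = {"x->m": 0.6, "m->y": 0.5, "x~~x": 1.0, "m~~m": 0.64, "y~~y": 0.75}
        # chosen so all implied variances are 1: standardized == raw
        sigma = implied_covariance(vals, spec)
        assert np.allclose(np.diag(sigma.values), 1.0)
        fit = fit_multigroup([GroupSample("g", sigma, 500)], spec)
        te = total_effects(fit)["g"]
        assert te.loc["y", "x"] == pytest.approx(0.6 * 0.5, abs=1e-6)

    def test_total_effect_matches_brute_force_path_enumeration(self):
        spec = herbivory_nodulation_spec()
        sigma = implied_covariance(TRUE, spec)
        fit = fit_multigroup(
            [GroupSample("sun", sigma, 600), GroupSample("shade", sigma, 600)], spec
        )
        std = fit.standardized["sun"]
        # enumerate every directed path herbivory -> ... -> nodules
        brute = (
            std["herbivory->nodules"]
            + std["herbivory->root"] * std["root->nodules"]
            + std["herbivory->shoot"] * std["shoot->nodules"]
        )
        te = fit.total_effects()["sun"].loc["nodules", "herbivory"]
        assert te == pytest.approx(brute, abs=1e-10)

    def test_zero_coefficients_give_zero_total_effects(self):
        spec = parse_model("x -> y")
        sigma = implied_covariance({"x->y": 0.0, "x~~x": 1.0, "y~~y": 1.0}, spec)
        fit = fit_multigroup([GroupSample("g", sigma, 100)], spec)
        assert np.abs(fit.total_effects()["g"].to_numpy()).max() < 1e-8

    def test_standardized_equals_unstandardized_at_unit_variances(self):
        spec = parse_model("x -> y")
        vals = {"x->y": 0.6, "x~~x": 1.0, "y~~y": 0.64}
        sigma = implied_covariance(vals, spec)
        fit = fit_multigroup([GroupSample("g", sigma, 300)], spec)
        assert fit.standardized["g"]["x->y"] == pytest.approx(
            fit.estimates["g"]["x->y"], abs=1e-6
        )

    def test_fit_indices_closed_form(self):
        # chi2 <= df -> perfect fit indices
        S = [np.array([[1.0, 0.5], [0.5, 1.0]])]
        n = np.array([101.0])
        cfi, rmsea = fit_indices(0.3, 1, S, n, 1)
        assert cfi == 1.0 and rmsea == 0.0
        # chi2 equal to the baseline at equal df -> CFI = 0
        Fb = float(np.log(1.0) * 2 - np.linalg.slogdet(S[0])[1])
        chi2_b = (101 - 1) * Fb
        cfi0, _ = fit_indices(chi2_b, 1, S, n, 1)
        assert cfi0 == pytest.approx(0.0, abs=1e-12)
        # hand computation of RMSEA scaling in N at fixed discrepancy
        F_fixed = 0.02
        for N in (101, 201):
            chi2 = (N - 1) * F_fixed
            _, rm = fit_indices(chi2, 1, S, np.array([float(N)]), 1)
            assert rm == pytest.approx(np.sqrt((chi2 - 1) / (1 * (N - 1))), abs=1e-12)

    def test_critical_ratio_formula(self):
        spec = herbivory_nodulation_spec()
        d1 = simulate_group(TRUE, spec, 500, rng=7)
        t2 = dict(TRUE, **{"root->nodules": 0.2})
        d2 = simulate_group(t2, spec, 500, rng=8)
        samples = [
            GroupSample(
                g,
                CovMatrix(list(spec.variables), np.cov(d.to_numpy(), rowvar=False), 500),
                500,
            )
            for g, d in (("sun", d1), ("shade", d2))
        ]
        fit = PathModel(samples, spec).fit()
        cr = fit.critical_ratios().set_index("parameter")
        row = cr.loc["root->nodules"]
        se = fit.standard_errors
        manual = (row["sun"] - row["shade"]) / np.sqrt(
            se["sun"]["root->nodules"] ** 2 + se["shade"]["root->nodules"] ** 2
        )
        assert row["z"] == pytest.approx(manual, rel=1e-10)
        assert row["p"] < 0.001  # injected difference is large
        # the constrained parameter is excluded
        assert "root~~shoot" not in cr.index
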