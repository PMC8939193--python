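"""Design assembly, penalized IRLS and REML smoothing selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ordsmooth import (
    ModelSpec,
    OrdinalTerm,
    build_design,
    fit_gam,
    generate_ordinal_glm,
    pirls,
    reml_criterion,
)
from ordsmooth.fit import optimize_smoothing


class TestBuildDesign:
    def test_no_ordinal_terms_reduces_to_glm_design(self, bpd_null_table, confounder_spec):
        table, _ = bpd_null_table
        d = build_design(confounder_spec, table)
        assert d.X.shape == (100, 7)
        assert d.penalties == []
        assert d.column_names[0] == "(Intercept)"

    def test_full_cohort_model_has_25_columns(self, bpd_null_table, full_spec):
        # intercept + 6 parametric + 3 blocks of (7 - 1) constrained columns
        table, _ = bpd_null_table
        d = build_design(full_spec, table)
        assert d.p == 1 + 6 + 3 * 6 == 25
        for name, sl, S, block in d.penalties:
            assert S.shape == (6, 6)
            assert sl.stop - sl.start == 6

    def test_duplicate_term_name_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModelSpec("y", "binomial", ("x",), (OrdinalTerm("x", 5, 1),))

    def test_missing_column_and_response_overlap(self, bpd_null_table):
        table, _ = bpd_null_table
        with pytest.raises(KeyError):
            build_design(ModelSpec("bpd", "binomial", ("nope",), ()), table)
        with pytest.raises(ValueError, match="predictor"):
            ModelSpec("bpd", "binomial", ("bpd",), ())

    def test_missing_rows_dropped_with_count(self, bpd_null_table, confounder_spec):
        table, _ = bpd_null_table
        table = table.copy()
        table.loc[[3, 11], "weight_g"] = np.nan
        d = build_design(confounder_spec, table)
        assert d.n == 98
        assert d.n_dropped == 2


class TestPirls:
    def test_gaussian_identity_is_one_step_ridge(self):
        table, _ = generate_ordinal_glm(80, 5, "gaussian", "linear", seed=1)
        spec = ModelSpec("y", "gaussian", (), (OrdinalTerm("x", 5, 2),))
        d = build_design(spec, table)
        lam = np.array([3.7])
        res = pirls(d, lam)
        S = d.penalty_total(lam)
        closed = np.linalg.solve(d.X.T @ d.X + S, d.X.T @ d.y)
        assert np.allclose(res.beta, closed, atol=1e-10)
        assert res.converged

    def test_binomial_small_lambda_matches_unpenalized_glm(self, simple_glm_table):
        table, _ = simple_glm_table
        spec = ModelSpec("y", "binomial", ("z1",), (OrdinalTerm("x", 5, 1),))
        d = build_design(spec, table)
        res = pirls(d, np.array([1e-10]))
        oracle = sm.GLM(d.y, d.X, family=sm.families.Binomial()).fit()
        assert np.allclose(res.beta, oracle.params, atol=1e-6)

    def test_penalty_prevents_separation_divergence(self):
        # level 5 is perfectly separated (all events): the unpenalized MLE
        # diverges there, the penalized fit must stay finite
        rng = np.random.default_rng(5)
        x = np.repeat([1, 2, 3, 4, 5], 30)
        p_base = np.array([0.3, 0.4, 0.5, 0.6, 1.0])
        y = rng.binomial(1, p_base[x - 1])
        table = pd.DataFrame({"y": y, "x": x})
        spec = ModelSpec("y", "binomial", (), (OrdinalTerm("x", 5, 1),))
        d = build_design(spec, table)
        res = pirls(d, np.array([1.0]))
        assert res.converged
        assert np.all(np.isfinite(res.beta))
        assert np.isfinite(res.penalized_deviance)
        assert np.max(np.abs(res.beta)) < 20

    def test_wrong_lambda_length_rejected(self, simple_glm_table):
        table, _ = simple_glm_table
        d = build_design(ModelSpec("y", "binomial", (), (OrdinalTerm("x", 5, 1),)), table)
        with pytest.raises(ValueError, match="smoothing parameters"):
            pirls(d, np.array([1.0, 2.0]))


@pytest.fixture(scope="module")
def gaussian_design():
    table, _ = generate_ordinal_glm(120, 6, "gaussian", "linear", seed=5)
    rng = np.random.default_rng(17)
    table["z1"] = rng.normal(size=len(table))
    spec = ModelSpec("y", "gaussian", ("z1",), (OrdinalTerm("x", 6, 1),))
    return build_design(spec, table)


class TestRemlCriterion:
    @staticmethod
    def mixed_model_reml_oracle(design, lam, phi):
        """Closed-form restricted log-likelihood of the equivalent linear
        mixed model: the smooth coefficients are random effects with
        covariance phi * (lam * S)^-1, fixed effects are flat-prior."""
        X, y = design.X, design.y
        sl = design.term_map["x"]
        S = design.penalties[0][2]
        Xf, Xr = X[:, :2], X[:, sl]
        V = phi * (np.eye(len(y)) + Xr @ np.linalg.solve(lam * S, Xr.T))
        Vi = np.linalg.inv(V)
        XtVX = Xf.T @ Vi @ Xf
        P = Vi - Vi @ Xf @ np.linalg.solve(XtVX, Xf.T @ Vi)
        _, ld_V = np.linalg.slogdet(V)
        _, ld_X = np.linalg.slogdet(XtVX)
        n, M_f = len(y), 2
        return 0.5 * (ld_V + ld_X + y @ P @ y + (n - M_f) * np.log(2 * np.pi))

    @pytest.mark.parametrize("log_lam", [-3.0, 0.0, 2.5, 6.0])
    def test_gaussian_criterion_equals_mixed_model_reml(self, gaussian_design, log_lam):
        phi = 1.3
        mine = reml_criterion(gaussian_design, [log_lam], scale=phi)
        oracle = self.mixed_model_reml_oracle(gaussian_design, np.exp(log_lam), phi)
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_criterion_continuous_at_large_lambda(self, gaussian_design):
        # smooth behaviour on the lambda -> infinity plateau
        vals = [reml_criterion(gaussian_design, [ll]) for ll in (9.0, 9.1, 9.2)]
        d1 = vals[1] - vals[0]
        d2 = vals[2] - vals[1]
        assert abs(d2 - d1) < 0.1 * max(abs(d1), 1e-3) + 1e-3

    def test_grid_minimum_is_interior_for_smooth_effect(self):
        wiggly = np.array([0.0, 1.0, -0.6, 0.8, -0.9, 0.7, -0.5])
        table, _ = generate_ordinal_glm(2000, 7, "gaussian", wiggly, seed=2)
        d = build_design(ModelSpec("y", "gaussian", (), (OrdinalTerm("x", 7, 2),)), table)
        grid = np.linspace(-8, 8, 41)
        vals = np.array([reml_criterion(d, [g]) for g in grid])
        assert np.all(np.isfinite(vals))
        imin = int(np.argmin(vals))
        assert 0 < imin < 40  # interior minimum on the grid

    def test_ml_variant_finite_and_distinct(self, gaussian_design):
        reml = reml_criterion(gaussian_design, [0.5], method="REML")
        ml = reml_criterion(gaussian_design, [0.5], method="ML")
        assert np.isfinite(ml) and ml != pytest.approx(reml)


class TestOptimizeSmoothing:
    def test_null_effect_typically_drives_lambda_to_upper_boundary(self, caplog):
        """Under a null ordinal effect the REML variance component is
        usually estimated at zero (lambda at the search boundary, effect
        collapsed to a constant) — though on individual draws an interior
        optimum is legitimate, so the check is over several draws."""
        spec = ModelSpec("y", "gaussian", (), (OrdinalTerm("x", 6, 1),))
        at_boundary = 0
        with caplog.at_level("WARNING"):
            for seed in (0, 1, 2, 5):
                table, _ = generate_ordinal_glm(2000, 6, "gaussian", "null", seed=seed)
                d = build_design(spec, table)
                lam, crit, _ = optimize_smoothing(d)
                if np.log(lam[0]) > 8:
                    at_boundary += 1
                    res = pirls(d, lam)
                    levels = d.blocks["x"].transform @ res.beta[d.term_map["x"]]
                    assert np.ptp(levels) < 1e-3
        assert at_boundary >= 3
        assert "boundary" in caplog.text

    def test_interior_optimum_is_local_minimum(self):
        wiggly = np.array([0.0, 1.0, -0.6, 0.8, -0.9, 0.7, -0.5])
        table, _ = generate_ordinal_glm(2000, 7, "gaussian", wiggly, seed=2)
        d = build_design(ModelSpec("y", "gaussian", (), (OrdinalTerm("x", 7, 2),)), table)
        lam, crit, _ = optimize_smoothing(d)
        ll = np.log(lam[0])
        assert abs(ll) < 11.5
        assert reml_criterion(d, [ll - np.log(10)]) > crit
        assert reml_criterion(d, [ll + np.log(10)]) > crit

    def test_per_term_selection_null_vs_active(self):
        wiggly = np.array([0.0, 1.2, -0.7, 1.0, -1.1, 0.8])
        table, _ = generate_ordinal_glm(800, 6, "binomial", wiggly, seed=4)
        rng = np.random.default_rng(9)
        table["x2"] = rng.integers(1, 7, size=len(table))
        spec = ModelSpec("y", "binomial", (), (OrdinalTerm("x", 6, 1), OrdinalTerm("x2", 6, 1)))
        fit = fit_gam(spec, table)
        assert np.log(fit.lambda_[0]) < 11.5      # active term: interior
        assert np.log(fit.lambda_[1]) > 8         # null term: boundary
        assert fit.edf["x"] > 1.5
        assert fit.edf["x2"] < 0.05


class TestFitGam:
    def test_intercept_only_binomial(self, bpd_null_table):
        table, _ = bpd_null_table
        fit = fit_gam(ModelSpec("bpd", "binomial", (), ()), table)
        p_hat = table["bpd"].mean()
        assert fit.beta[0] == pytest.approx(np.log(p_hat / (1 - p_hat)), abs=1e-8)
        assert fit.edf_total == pytest.approx(1.0, abs=1e-8)

    def test_no_smooth_terms_matches_glm_oracle(self, bpd_null_table, confounder_spec):
        table, _ = bpd_null_table
        fit = fit_gam(confounder_spec, table)
        oracle = sm.GLM(fit.design.y, fit.design.X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.beta, oracle.params, atol=1e-6)
        assert np.allclose(np.sqrt(np.diag(fit.Vb)), oracle.bse, atol=1e-6)

    def test_deviance_not_above_null_deviance(self, bpd_null_table, full_spec):
        table, _ = bpd_null_table
        fit = fit_gam(full_spec, table)
        assert fit.deviance <= fit.null_deviance + 1e-8
        assert fit.converged
        for name, edf in fit.edf.items():
            assert 0 <= edf <= 6 + 1e-6
        assert fit.edf_total <= fit.design.p
        evals = np.linalg.eigvalsh(fit.Vb)
        assert evals.min() > -1e-8

    def test_edf_monotone_in_lambda(self):
        table, _ = generate_ordinal_glm(300, 6, "gaussian", "linear", seed=8)
        spec = ModelSpec("y", "gaussian", (), (OrdinalTerm("x", 6, 1),))
        edfs = [
            fit_gam(spec, table, lambda_=[lam]).edf["x"]
            for lam in np.exp(np.linspace(-6, 8, 8))
        ]
        assert all(a >= b - 1e-9 for a, b in zip(edfs, edfs[1:]))

    def test_selected_lambda_beats_grid(self):
        table, _ = generate_ordinal_glm(500, 6, "binomial", "linear", seed=21)
        spec = ModelSpec("y", "binomial", (), (OrdinalTerm("x", 6, 2),))
        fit = fit_gam(spec, table)
        d = build_design(spec, table)
        grid_vals = [reml_criterion(d, [g]) for g in np.linspace(-10, 10, 21)]
        assert fit.criterion <= min(grid_vals) + 1e-5

    def test_gaussian_scale_estimated(self):
        table, _ = generate_ordinal_glm(400, 5, "gaussian", "linear", seed=13, noise_sd=2.0)
        fit = fit_gam(ModelSpec("y", "gaussian", (), (OrdinalTerm("x", 5, 2),)), table)
        assert 3.0 < fit.scale < 5.5  # around sigma^2 = 4
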