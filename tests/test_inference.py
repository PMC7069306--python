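import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

from mgsalloc import (
    GeneratorConfig,
    StudyConfig,
    generate_population,
    build_mating_graph,
    compute_mgs,
    build_analysis_table,
    fit_lmm,
    vif,
    pearson_r,
    likelihood_ratio_test,
    marginal_line,
)
from mgsalloc.inference import PREDICTORS, RESPONSES, lrt_drop_predictor, sign_stability
from mgsalloc.simulate import DEFAULT_NOISE

ZERO_NOISE = {k: (0.0, 0.0) for k in DEFAULT_NOISE}

#: Published sex-allocation coefficient table used for the marginal lines.
SEX_ALLOC_COEFS = {
    "intercept": 0.1084,
    "mgs_m": 0.0089,
    "mgs_f": -0.0083,
    "body_weight": -0.000020,
}


def make_table(**gen_kw):
    defaults = dict(n_shells=12, seed=5)
    defaults.update(gen_kw)
    cfg = GeneratorConfig(**defaults)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, truth = generate_population(cfg)
    sc = StudyConfig(elongation_factor=cfg.elongation_factor)
    table = build_analysis_table(records, compute_mgs(build_mating_graph(records, sc)), sc)
    return table, truth


class TestFitLMM:
    def test_zero_noise_exact_recovery_all_responses(self):
        table, truth = make_table(mode="organ_level", noise=ZERO_NOISE, seed=11)
        assert truth.n_floored == 0
        for resp in RESPONSES[:3]:
            fit = fit_lmm(table, resp)
            coefs = truth.coefficient_sets[resp]
            assert fit.params["intercept"] == pytest.approx(coefs.intercept, abs=1e-8)
            assert fit.params["mgs_m"] == pytest.approx(coefs.mgs_m, abs=1e-8)
            assert fit.params["mgs_f"] == pytest.approx(coefs.mgs_f, abs=1e-8)
            assert fit.params["body_weight"] == pytest.approx(coefs.body, abs=1e-10)
            assert fit.method == "exact"

    def test_zero_noise_allocation_mode_recovery(self):
        table, truth = make_table(mode="allocation_level", noise=ZERO_NOISE, seed=3)
        fit = fit_lmm(table, "sex_allocation")
        coefs = truth.coefficient_sets["sex_allocation"]
        assert fit.params["mgs_m"] == pytest.approx(coefs.mgs_m, abs=1e-8)
        assert fit.params["mgs_f"] == pytest.approx(coefs.mgs_f, abs=1e-8)

    def test_zero_shell_variance_boundary(self):
        noise = dict(DEFAULT_NOISE)
        noise["sex_allocation"] = (0.0, 0.02)
        table, _ = make_table(mode="allocation_level", noise=noise,
                              n_shells=60, seed=19)
        fit = fit_lmm(table, "sex_allocation")
        # boundary estimate: shell variance near zero, tiny share of residual
        assert fit.re_var <= 0.2 * fit.resid_var

    def test_single_shell_is_hard_error(self, study_config):
        table, _ = make_table(n_shells=6, seed=2)
        one = table[table["shell_id"] == table["shell_id"].iloc[0]]
        with pytest.raises(ValueError, match="single shell"):
            fit_lmm(one, "sex_allocation")

    def test_perfect_collinearity_is_hard_error(self):
        table, _ = make_table(seed=2)
        table = table.copy()
        table["dup"] = table["mgs_m"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            fit_lmm(table, "sex_allocation", ["mgs_m", "dup"])

    def test_matches_lme4_oracle(self, tmp_path):
        """Dual-route check: REML fit agrees with R lme4 on the same table."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        table, _ = make_table(n_shells=30, seed=7)
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "fit <- lmer(sex_allocation ~ mgs_m + mgs_f + body_weight"
            " + (1|shell_id), data=d, REML=TRUE)\n"
            "cat(sprintf('%.12g\\n', fixef(fit)))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        r_coefs = [float(v) for v in out.stdout.split()]
        fit = fit_lmm(table, "sex_allocation")
        ours = [fit.params[k] for k in ["intercept", *PREDICTORS]]
        np.testing.assert_allclose(ours, r_coefs, rtol=1e-4)


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        t = pd.DataFrame({"u": [1.0, 1, -1, -1], "v": [1.0, -1, 1, -1]})
        out = vif(t, ["u", "v"])
        assert out["u"] == pytest.approx(1.0, abs=1e-12)
        assert out["v"] == pytest.approx(1.0, abs=1e-12)

    def test_correlation_0_75_gives_closed_form(self):
        # y = 0.75 x + sqrt(1 - 0.75^2) z with z orthonormal to x:
        # sample correlation is exactly 0.75, VIF = 1/(1-0.5625)
        u = np.array([1.0, 1, -1, -1])
        v = np.array([1.0, -1, 1, -1])
        t = pd.DataFrame({"x": u, "y": 0.75 * u + np.sqrt(1 - 0.75**2) * v})
        out = vif(t, ["x", "y"])
        assert out["x"] == pytest.approx(1 / (1 - 0.5625), rel=1e-9)
        assert out["y"] == pytest.approx(2.2857142857, rel=1e-6)

    def test_duplicated_predictor_reported_infinite(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        out = vif(t, ["a", "b"])
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_vif_at_least_one_on_real_tables(self):
        table, _ = make_table(n_shells=25, seed=13)
        out = vif(table, PREDICTORS)
        assert all(v >= 1.0 - 1e-9 for v in out.values())

    def test_zero_variance_predictor_is_hard_error(self):
        t = pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="zero variance"):
            vif(t, ["a", "b"])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_cancelling_cross_products_give_zero(self):
        r, _ = pearson_r([0.0, 1, 2], [0.0, 1, 0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_is_hard_error(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1, 1], [1.0, 2, 3])


class TestLRT:
    def test_closed_form_reproduces_published_statistic(self):
        chi2, df, p = likelihood_ratio_test(-10.0, -11.9345, df=1)
        assert chi2 == pytest.approx(3.869)
        assert round(p, 3) == 0.049

    def test_identical_models_give_zero_and_one(self):
        chi2, df, p = likelihood_ratio_test(-5.0, -5.0, df=1)
        assert chi2 == 0.0 and p == 1.0

    def test_negative_statistic_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            chi2, _, p = likelihood_ratio_test(-6.0, -5.0, df=1)
        assert chi2 == 0.0 and p == 1.0

    def test_requires_ml_fits(self):
        table, _ = make_table(n_shells=20, seed=3)
        full = fit_lmm(table, "sex_allocation", PREDICTORS)  # REML
        reduced = fit_lmm(table, "sex_allocation", ["mgs_m", "body_weight"])
        with pytest.raises(ValueError, match="maximum likelihood"):
            likelihood_ratio_test(full, reduced)

    def test_non_nested_is_hard_error(self):
        table, _ = make_table(n_shells=20, seed=3)
        a = fit_lmm(table, "sex_allocation", ["mgs_m"], reml=False)
        b = fit_lmm(table, "sex_allocation", ["mgs_f"], reml=False)
        with pytest.raises(ValueError, match="subset"):
            likelihood_ratio_test(a, b)

    def test_drop_mgsf_runs_on_fitted_models(self):
        table, _ = make_table(n_shells=30, seed=7)
        chi2, df, p = lrt_drop_predictor(table, "sex_allocation", "mgs_f")
        assert chi2 >= 0 and df == 1 and 0 <= p <= 1


class TestMarginalLine:
    def test_published_line_versus_mgsm(self):
        line = marginal_line(
            SEX_ALLOC_COEFS, "mgs_m", {"mgs_f": 3, "body_weight": 1014.18}
        )
        assert round(line.slope, 4) == 0.0089
        assert round(line.intercept, 4) == 0.0632

    def test_published_line_versus_mgsf(self):
        line = marginal_line(
            SEX_ALLOC_COEFS, "mgs_f", {"mgs_m": 3, "body_weight": 1014.18}
        )
        assert round(line.slope, 4) == -0.0083
        assert round(line.intercept, 4) == 0.1148

    def test_zero_held_values_leave_intercept(self):
        line = marginal_line(SEX_ALLOC_COEFS, "mgs_m", {"mgs_f": 0, "body_weight": 0})
        assert line.intercept == SEX_ALLOC_COEFS["intercept"]

    def test_missing_held_value_is_hard_error(self):
        with pytest.raises(ValueError, match="held values missing"):
            marginal_line(SEX_ALLOC_COEFS, "mgs_m", {"mgs_f": 3})

    def test_line_from_fitted_model_predicts_fit(self):
        table, _ = make_table(n_shells=25, seed=13)
        fit = fit_lmm(table, "sex_allocation")
        held = {"mgs_f": 3.0, "body_weight": 800.0}
        line = marginal_line(fit, "mgs_m", held)
        for x in (2.0, 5.0):
            expected = (
                fit.params["intercept"]
                + fit.params["mgs_m"] * x
                + fit.params["mgs_f"] * held["mgs_f"]
                + fit.params["body_weight"] * held["body_weight"]
            )
            assert line.predict(x) == pytest.approx(expected, abs=1e-12)


def test_sign_stability_on_clean_simulation():
    table, _ = make_table(mode="allocation_level", n_shells=120, seed=21)
    stable = sign_stability(table, "sex_allocation", ["mgs_m", "mgs_f"])
    assert isinstance(stable, dict) and set(stable) == {"mgs_m", "mgs_f"}
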