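import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import gazegrid as gg
from gazegrid import glmm
from gazegrid.glmm import (
    ModelSpec,
    RandomEffects,
    comparison_spec,
    conditional_mode_intervals,
    count_parameters,
    derived_fixed_coefficient,
    enumerate_control_specs,
    individual_coefficients,
    information_criteria,
    lrt,
    marginal_conditional_r2,
    parse_formula,
    partial_effects,
    propose_simplification,
    wald_table,
)

from conftest import make_dummy_fit


def _random_glm_dataset(rng, n=300):
    t = pd.DataFrame(
        {
            "subject": rng.choice(list("abcde"), n),
            "image": rng.choice([f"i{j}" for j in range(8)], n),
            "x1": rng.standard_normal(n),
            "x2": rng.standard_normal(n),
        }
    )
    eta = rng.normal(-0.4, 0.1) + 0.7 * t.x1 - 0.5 * t.x2
    t["fixated"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return t


class TestSpecAndFormula:
    def test_formula_roundtrip(self):
        f = "fixated ~ 1 + cb_z + sal_z + (1 + cb_z + sal_z | subject) + (1 + cb_z + sal_z || image)"
        spec = parse_formula(f)
        assert spec.fixed == ("1", "cb_z", "sal_z")
        assert spec.random[0].correlated and not spec.random[1].correlated
        assert parse_formula(spec.formula()).formula() == spec.formula()

    def test_intercept_implicit(self):
        spec = parse_formula("y ~ x + (x | g)")
        assert spec.fixed[0] == "1"
        assert spec.random[0].terms[0] == "1"

    def test_random_slope_requires_fixed_term(self):
        with pytest.raises(ValueError, match="not a fixed term"):
            ModelSpec(response="y", fixed=("1",), random=(RandomEffects("g", ("1", "x")),))

    def test_bad_formula(self):
        with pytest.raises(ValueError):
            parse_formula("no tilde here")

    def test_structure_labels(self):
        assert RandomEffects("g", ("1", "x"), True).structure == "maximal"
        assert RandomEffects("g", ("1", "x"), False).structure == "zcp"
        assert RandomEffects("g", ("1",)).structure == "intercept"


class TestParameterCounts:
    def test_two_predictor_maximal_is_12(self, two_predictor_specs):
        kf, kv, kc = count_parameters(two_predictor_specs["maximal"])
        assert (kf, kv + kc) == (3, 12)

    def test_comparison_counts(self):
        spec = comparison_spec(["AWS", "IKN98", "GBVS"], "AWS")
        kf, kv, kc = count_parameters(spec)
        assert kf == 7  # intercept, 2 simple effects, 4 interactions
        assert kv + kc == 56  # per factor: 7 variances + 21 correlations
        zcp = comparison_spec(["AWS", "IKN98", "GBVS"], "AWS", structure="zcp")
        _, kv, kc = count_parameters(zcp)
        assert kv == 14 and kc == 0

    def test_two_map_comparison(self):
        kf, _, _ = count_parameters(comparison_spec(["A", "B"], "A"))
        assert kf == 5  # 1 + 2 + 2x1

    def test_reference_must_exist(self):
        with pytest.raises(ValueError, match="reference"):
            comparison_spec(["A", "B"], "C")

    def test_control_grid_has_189_specs(self):
        cb_names = [f"cb{i}" for i in range(7)]
        specs = enumerate_control_specs(
            ["IKN98", "AWS", "GBVS"], cb_names, [(100, 100), (50, 50), (200, 200)]
        )
        assert len(specs) == 189
        structures = {s["structure"] for s in specs}
        assert structures == {"maximal", "zcp", "intercept"}


class TestWorkedArithmetic:
    def test_derived_coefficient_sums_terms(self):
        fixed = pd.DataFrame(
            {"b": [-0.570, 0.293], "se": [0.033, 0.031], "z": [0.0, 0.0], "p": [1.0, 1.0]},
            index=["cb_z", "map[GBVS]:cb_z"],
        )
        fit = make_dummy_fit(fixed)
        assert derived_fixed_coefficient(fit, "cb_z", "map[GBVS]:cb_z") == pytest.approx(-0.277)
        assert derived_fixed_coefficient(fit, "map[GBVS]:cb_z", "cb_z") == pytest.approx(-0.277)

    def test_derived_coefficient_zero_interaction(self):
        fixed = pd.DataFrame(
            {"b": [0.5, 0.0], "se": [0.1, 0.1], "z": [0.0, 0.0], "p": [1.0, 1.0]},
            index=["a", "b"],
        )
        assert derived_fixed_coefficient(make_dummy_fit(fixed), "a", "b") == 0.5

    def test_individual_coefficient_from_mode(self):
        fixed = pd.DataFrame(
            {"b": [0.72], "se": [0.03], "z": [24.0], "p": [0.0]}, index=["sal_z"]
        )
        modes = pd.DataFrame({"sal_z": [-0.75, 0.10]}, index=["scene139", "scene1"])
        fit = make_dummy_fit(fixed, cond_modes={"image": modes})
        coefs = individual_coefficients(fit, "image", "sal_z")
        assert coefs["scene139"] == pytest.approx(-0.03)
        assert coefs["scene1"] == pytest.approx(0.82)

    def test_r2_arithmetic(self):
        # sigma_f^2 = 1, sum of random variances = 1, logit residual pi^2/3
        rng = np.random.default_rng(0)
        eta = rng.standard_normal(2000)
        eta = (eta - eta.mean()) / eta.std()  # population variance exactly 1
        fixed = pd.DataFrame({"b": [0.0], "se": [1.0], "z": [0.0], "p": [1.0]}, index=["intercept"])
        fit = make_dummy_fit(
            fixed, fitted_fixed_linear=eta, random_design_var={"subject": 1.0},
            fitted_linear=eta, fitted_mean=np.full(eta.size, 0.5), n_obs=eta.size,
        )
        r2m, r2c = marginal_conditional_r2(fit)
        assert r2m == pytest.approx(1.0 / (2.0 + np.pi**2 / 3.0), abs=1e-12)
        assert r2c == pytest.approx(2.0 / (2.0 + np.pi**2 / 3.0), abs=1e-12)

    def test_wald_identities(self):
        fixed = pd.DataFrame(
            {"b": [0.0, 1.2, -0.3], "se": [0.5, 0.4, 0.1], "z": 0.0, "p": 0.0},
            index=["a", "b", "c"],
        )
        out = wald_table(make_dummy_fit(fixed))
        assert out.loc["a", "z"] == 0.0 and out.loc["a", "p"] == 1.0
        assert np.allclose(out["z"], fixed["b"] / fixed["se"], atol=1e-10)


class TestFitting:
    def test_oracle_equivalence_degenerate_random(self):
        # with the random structure pinned near zero the fit must agree
        # with an independent IRLS GLM
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        spec = parse_formula("fixated ~ x1 + x2 + (1|subject) + (1|image)")
        for _ in range(5):
            t = _random_glm_dataset(rng)
            fit = glmm.fit(spec, t, fix_theta=np.array([1e-7, 1e-7]))
            X = sm.add_constant(t[["x1", "x2"]])
            ref = sm.GLM(t["fixated"], X, family=sm.families.Binomial()).fit()
            assert np.abs(fit.fixed["b"].to_numpy() - ref.params.to_numpy()).max() < 1e-4
            assert np.abs(fit.fixed["se"].to_numpy() - ref.bse.to_numpy()).max() < 1e-4

    def test_deterministic_refit(self, small_table, two_predictor_specs):
        table, _ = small_table
        f1 = glmm.fit(two_predictor_specs["zcp"], table)
        f2 = glmm.fit(two_predictor_specs["zcp"], table)
        assert np.abs(f1.fixed["b"] - f2.fixed["b"]).max() < 1e-8
        assert np.abs(f1.theta - f2.theta).max() < 1e-8

    def test_pirls_monotone_in_iterations(self, small_table, two_predictor_specs):
        # accepted PIRLS steps never increase the penalized deviance
        table, _ = small_table
        spec = two_predictor_specs["intercept"]
        fam = glmm._Family.make("binomial")
        y = table["fixated"].to_numpy(float)
        X, names = glmm.build_design(spec, table, list(spec.fixed))
        blocks = glmm._make_blocks(spec, table)
        ws = glmm._Workspace(X, blocks)
        lams = [b.lam(np.array([1.0])) for b in blocks]
        pdevs = []
        for iters in range(1, 7):
            out = glmm._pirls(
                fam, y, ws, blocks, lams,
                np.zeros(ws.qr), np.zeros(X.shape[1]), tol=0.0, max_iter=iters,
            )
            pdevs.append(out[4])
        assert all(b <= a + 1e-8 for a, b in zip(pdevs, pdevs[1:]))

    def test_unknown_column_error_names_column(self, small_table):
        table, _ = small_table
        with pytest.raises(KeyError, match="nonexistent"):
            glmm.fit(parse_formula("fixated ~ nonexistent + (1|subject) + (1|image)"), table)

    def test_poisson_path_recovers_rate(self):
        rng = np.random.default_rng(5)
        n = 2000
        t = pd.DataFrame(
            {
                "subject": rng.choice(list("abcdefgh"), n),
                "image": rng.choice([f"i{j}" for j in range(12)], n),
                "x": rng.standard_normal(n),
            }
        )
        t["count"] = rng.poisson(np.exp(0.3 + 0.5 * t.x))
        fit = glmm.fit(parse_formula("count ~ x + (1|subject) + (1|image)", family="poisson"), t)
        assert fit.fixed.loc["x", "b"] == pytest.approx(0.5, abs=0.08)
        assert fit.fixed.loc["intercept", "b"] == pytest.approx(0.3, abs=0.1)

    def test_binomial_rejects_counts(self, small_table):
        table, _ = small_table
        bad = table.assign(fixated=table["count"] + 1)
        with pytest.raises(ValueError, match="0/1"):
            glmm.fit(parse_formula("fixated ~ cb_z + (1|subject) + (1|image)"), bad)

    def test_matches_lme4_glmer(self, tmp_path):
        # cross-implementation check against the reference mixed-model
        # fitter at the same (profiled-Laplace) objective
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        params = gg.GenerativeParams(n_subjects=10, n_images=12)
        table, _ = gg.simulate_recovery_table(params, seed=11)
        csv = tmp_path / "d.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            m <- glmer(fixated ~ cb_z + sal_z + (cb_z + sal_z || subject) +
                       (cb_z + sal_z || image), data = d, family = binomial, nAGQ = 0)
            cat(fixef(m), as.numeric(logLik(m)), sep = ',')
            """
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        ref = np.array([float(v) for v in res.stdout.strip().split(",")])
        fit = glmm.fit(
            parse_formula("fixated ~ cb_z + sal_z + (cb_z + sal_z || subject) + (cb_z + sal_z || image)"),
            table,
        )
        assert np.abs(fit.fixed["b"].to_numpy() - ref[:3]).max() < 2e-3
        assert fit.loglik == pytest.approx(ref[3], abs=0.05)


class TestInference:
    def test_lrt_identical_models(self, nested_fits):
        chi2, df, p = lrt(nested_fits["zcp"], nested_fits["zcp"])
        assert df == 0 and abs(chi2) < 1e-8 and p == 1.0

    def test_lrt_structure_dfs(self, nested_fits):
        chi2_mz, df_mz, _ = lrt(nested_fits["zcp"], nested_fits["maximal"])
        assert df_mz == 6  # six dropped correlations
        chi2_zi, df_zi, p_zi = lrt(nested_fits["intercept"], nested_fits["zcp"])
        assert df_zi == 4  # four dropped slope variances
        assert chi2_zi >= -1e-6 and 0 <= p_zi <= 1

    def test_lrt_rejects_different_data(self, nested_fits, small_params):
        other, _ = gg.simulate_recovery_table(small_params, seed=99)
        fit_other = glmm.fit(
            parse_formula("fixated ~ cb_z + sal_z + (1|subject) + (1|image)"), other
        )
        with pytest.raises(ValueError, match="same data"):
            lrt(fit_other, nested_fits["maximal"])

    def test_lrt_rejects_non_nested(self, nested_fits, small_table):
        table, _ = small_table
        other = glmm.fit(parse_formula("fixated ~ cb_z + (1 + cb_z | subject) + (1|image)"), table)
        with pytest.raises(ValueError, match="not a subset|not nested"):
            lrt(nested_fits["maximal"], other)

    def test_information_criteria_identities(self, nested_fits):
        for fit in nested_fits.values():
            aic, bic = information_criteria(fit)
            assert aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
            assert bic - aic == pytest.approx(fit.n_params * (np.log(fit.n_obs) - 2))

    def test_slopes_justified_by_data(self, nested_fits):
        # data generated with real random slopes: zcp must beat the
        # intercept-only model on AIC
        aic_zcp, _ = information_criteria(nested_fits["zcp"])
        aic_int, _ = information_criteria(nested_fits["intercept"])
        assert aic_zcp < aic_int

    def test_conditional_modes_shrink_to_zero_mean(self, nested_fits):
        fit = nested_fits["maximal"]
        for factor in ("subject", "image"):
            modes = fit.cond_modes[factor]
            assert np.abs(modes.mean(axis=0)).max() < 0.15

    def test_conditional_mode_intervals(self, nested_fits):
        fit = nested_fits["maximal"]
        ci = conditional_mode_intervals(fit, "image")
        assert set(ci.columns) == {"level", "term", "mode", "lower", "upper"}
        half = (ci["upper"] - ci["lower"]) / 2
        sd = np.sqrt(np.concatenate([fit.cond_var["image"][t] for t in fit.cond_modes["image"].columns]))
        assert np.allclose(half, 1.96 * sd)

    def test_zero_variance_gives_zero_modes(self, small_table):
        table, _ = small_table
        spec = parse_formula("fixated ~ cb_z + (1|subject) + (1|image)")
        fit = glmm.fit(spec, table, fix_theta=np.array([0.0, 0.0]))
        assert np.abs(fit.cond_modes["subject"].to_numpy()).max() == 0.0
        ci = conditional_mode_intervals(fit, "subject")
        assert np.allclose(ci["upper"] - ci["lower"], 0.0)
        assert fit.singular  # flagged, never silent

    def test_individual_coefficients_mean_near_fixed(self, nested_fits):
        fit = nested_fits["maximal"]
        coefs = individual_coefficients(fit, "image", "sal_z")
        assert coefs.mean() == pytest.approx(fit.fixed.loc["sal_z", "b"], abs=0.12)

    def test_propose_simplification_lists_boundaries(self, small_table):
        table, _ = small_table
        fit = glmm.fit(
            parse_formula("fixated ~ cb_z + (1|subject) + (1|image)"), table,
            fix_theta=np.array([0.0, 1.0]),
        )
        flags = propose_simplification(fit)
        assert any("subject" in f and "variance" in f for f in flags)


class TestPartialEffects:
    def test_intercept_only_constant(self, nested_fits):
        fit = nested_fits["maximal"]
        vals = pd.DataFrame({"cb_z": np.linspace(-2, 2, 9), "sal_z": 0.0})
        eta = partial_effects(fit, ["intercept"], vals)
        assert np.allclose(eta, fit.fixed.loc["intercept", "b"])

    def test_affine_in_kept_slope(self, nested_fits):
        fit = nested_fits["maximal"]
        x = np.linspace(-2, 2, 9)
        vals = pd.DataFrame({"sal_z": x})
        eta = partial_effects(fit, ["intercept", "sal_z"], vals)
        b0 = fit.fixed.loc["intercept", "b"]
        b1 = fit.fixed.loc["sal_z", "b"]
        assert np.allclose(eta, b0 + b1 * x)
        # at the standardized mean the partial effect is the intercept
        assert eta[4] == pytest.approx(b0)

    def test_unknown_term_rejected(self, nested_fits):
        with pytest.raises(KeyError):
            partial_effects(nested_fits["maximal"], ["nope"], pd.DataFrame({"cb_z": [0.0]}))


@pytest.fixture(scope="module")
def comparison_fit():
    rng = np.random.default_rng(21)
    params = gg.GenerativeParams(n_subjects=6, n_images=8)
    table, _ = gg.simulate_recovery_table(params, seed=31)
    # second and third synthetic map variants: perturbed copies
    table["salA_z"] = table["sal_z"]
    for name, noise in (("salB_z", 0.6), ("salC_z", 0.9)):
        col = table["sal_z"] + noise * rng.standard_normal(len(table))
        table[name] = (col - col.mean()) / col.std(ddof=1)
    stacked = gg.stack_for_comparison(
        table, {"A": "salA_z", "B": "salB_z", "C": "salC_z"}, value_column="sal"
    )
    stacked["sal_z"] = stacked["sal"]
    spec = comparison_spec(["A", "B", "C"], "A", structure="zcp")
    return glmm.fit(spec, stacked, outer_ftol=1e-6), table


class TestComparisonModel:

    def test_seven_fixed_effects_with_treatment_names(self, comparison_fit):
        fit, _ = comparison_fit
        assert len(fit.fixed) == 7
        assert "map[B]:cb_z" in fit.fixed.index and "map[C]:sal_z" in fit.fixed.index
        assert "map[A]:cb_z" not in fit.fixed.index  # reference absorbed

    def test_reference_slope_recovered(self, comparison_fit):
        fit, _ = comparison_fit
        # reference map is the generative map: saliency simple effect near truth
        assert fit.fixed.loc["sal_z", "b"] == pytest.approx(0.7, abs=0.35)
        # noisier map variants predict less well: negative interactions
        assert fit.fixed.loc["map[C]:sal_z", "b"] < 0

    def test_derived_coefficient_consistency(self, comparison_fit):
        fit, _ = comparison_fit
        d = derived_fixed_coefficient(fit, "sal_z", "map[B]:sal_z")
        assert d == pytest.approx(
            fit.fixed.loc["sal_z", "b"] + fit.fixed.loc["map[B]:sal_z", "b"]
        )


class TestStandardizationInvariance:
    def test_affine_rescaling_of_raw_predictor(self, small_params):
        # fitted standardized slopes are invariant to affine rescaling of
        # the raw predictor before standardization
        table, _ = gg.simulate_recovery_table(small_params, seed=13)
        t1 = table.assign(raw=3.0 + 2.0 * table["sal_z"])
        t2 = table.assign(raw=-5.0 + 0.1 * table["sal_z"])
        spec = parse_formula("fixated ~ raw_z + (1|subject) + (1|image)")
        fits = []
        for t in (t1, t2):
            t = gg.standardize(t, ["raw"])
            fits.append(glmm.fit(spec, t, outer_ftol=1e-9))
        b1 = fits[0].fixed["b"].to_numpy()
        b2 = fits[1].fixed["b"].to_numpy()
        assert np.abs(np.abs(b1) - np.abs(b2)).max() < 1e-6
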