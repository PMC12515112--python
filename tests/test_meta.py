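"""Meta-models: stacking, weighted-LMM behavior and an external R oracle."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

from cesdemog import fit_weighted_lmm, stack_coefficients, temperature_gradient_prediction
from cesdemog.errors import DataError
from cesdemog.growth import GrowthCoefficients
from cesdemog.meta import metafits_to_frame
from cesdemog.simulate import CoefficientTruth, simulate_coefficient_table


def _growth(scheme, species, bs=0.02, bp=0.05, se=0.01):
    return GrowthCoefficients(
        scheme=scheme, species=species,
        beta_survival=bs, beta_survival_se=se,
        beta_productivity=bp, beta_productivity_se=se,
        intercept=0.0, n_years=8, r_squared=0.5,
    )


def _traits(species, migration="long-distance", habitat="forest"):
    return pd.DataFrame(
        {"species": species, "migration": migration, "habitat": habitat}
    )


def _temps(schemes, temp=10.0):
    return pd.DataFrame({"scheme": schemes, "mean_temp_c": temp})


class TestStacking:
    def test_two_rows_per_population_with_traits_joined(self):
        growth = [_growth("A", "SP1"), _growth("B", "SP2")]
        table = stack_coefficients(
            growth,
            _traits(["SP1", "SP2"], migration=["long-distance", "short/resident"]),
            _temps(["A", "B"], temp=[8.0, 15.0]),
        )
        assert len(table) == 4
        assert set(table["measure"]) == {"survival", "productivity"}
        row = table[(table["species"] == "SP2") & (table["measure"] == "survival")].iloc[0]
        assert row["migration"] == "short/resident"
        assert row["mean_temp_c"] == 15.0

    def test_missing_species_trait_is_keyerror(self):
        with pytest.raises(KeyError, match="SP2"):
            stack_coefficients([_growth("A", "SP2")], _traits(["SP1"]), _temps(["A"]))

    def test_missing_scheme_temperature_is_keyerror(self):
        with pytest.raises(KeyError, match="B"):
            stack_coefficients([_growth("B", "SP1")], _traits(["SP1"]), _temps(["A"]))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(DataError, match="non-positive"):
            stack_coefficients([_growth("A", "SP1", se=0.0)], _traits(["SP1"]), _temps(["A"]))


@pytest.fixture(scope="module")
def coef_table():
    return simulate_coefficient_table(
        CoefficientTruth(intercept=0.06, survival_effect=0.02),
        n_species=12, n_schemes=5, seed=7,
    )


class TestWeightedLMM:
    def test_zero_variance_limit_matches_wls_normal_equations(self, coef_table):
        """With the random-effect variances forced to zero the model is
        weighted least squares; compare against (X'WX)^-1 X'Wy directly."""
        fit = fit_weighted_lmm(coef_table, model="A", force_zero_random_effects=True)
        is_surv = (coef_table["measure"] == "survival").to_numpy(float)
        X = np.column_stack([np.ones(len(coef_table)), is_surv])
        w = 1.0 / coef_table["se"].to_numpy() ** 2
        y = coef_table["coefficient"].to_numpy()
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        np.testing.assert_allclose(fit.result.beta, beta, atol=1e-8)
        # residual-df t-tests in the WLS limit
        assert np.all(fit.result.df == len(coef_table) - 2)

    def test_measure_effect_recovers_simulated_gap(self, coef_table):
        fit = fit_weighted_lmm(coef_table, model="A")
        term = fit["measure[survival]"]
        assert term["estimate"] == pytest.approx(0.02, abs=3 * term["se"])
        assert term["se"] > 0
        assert term["p"] < 0.05  # effect 0.02 with se ~ 0.005 is detectable

    def test_weight_rescaling_leaves_estimates_and_se_unchanged(self, coef_table):
        """Multiplying every SE by a constant only rescales sigma^2 and
        the variance components; estimates, SEs and t-tests are invariant."""
        scaled = coef_table.copy()
        scaled["se"] = scaled["se"] * 3.0
        f1 = fit_weighted_lmm(coef_table, model="A")
        f2 = fit_weighted_lmm(scaled, model="A")
        np.testing.assert_allclose(f1.result.beta, f2.result.beta, atol=1e-8)
        np.testing.assert_allclose(f1.result.se, f2.result.se, rtol=1e-5)
        assert f2.result.sigma2 == pytest.approx(f1.result.sigma2 / 9.0, rel=1e-4)

    def test_model_b_and_c_designs_have_expected_terms(self, coef_table):
        fb = fit_weighted_lmm(coef_table, model="B")
        fc = fit_weighted_lmm(coef_table, model="C")
        assert fb.result.fixed_names == [
            "(Intercept)", "measure[survival]", "mean_temp", "measure[survival]:mean_temp",
        ]
        assert "measure[survival]:habitat[reed]" in fc.result.fixed_names
        assert set(fb.varcomps) == {"species", "residual"}
        assert set(fc.varcomps) == {"species", "scheme", "residual"}

    def test_unknown_model_rejected(self, coef_table):
        with pytest.raises(ValueError, match="unknown model"):
            fit_weighted_lmm(coef_table, model="D")

    def test_results_frame_stacks_models(self, coef_table):
        fits = [fit_weighted_lmm(coef_table, model=m) for m in ("A", "B")]
        frame = metafits_to_frame(fits)
        assert set(frame["model"]) == {"A", "B"}
        assert {"parameter", "estimate", "se", "df", "t", "p"} <= set(frame.columns)


class TestAgainstR:
    def test_model_a_matches_lmer_satterthwaite(self, coef_table, tmp_path):
        """Independent oracle: lme4/lmerTest fit of the same weighted
        model. Estimates and SEs must agree to ~1e-6, Satterthwaite
        dfs to ~0.1%, variance components to ~1e-6 relative."""
        data_csv = tmp_path / "table.csv"
        fixed_csv = tmp_path / "fixed.csv"
        vc_csv = tmp_path / "vc.csv"
        coef_table.to_csv(data_csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            """
            suppressMessages({library(lme4); library(lmerTest)})
            args <- commandArgs(trailingOnly = TRUE)
            d <- read.csv(args[1])
            d$measure <- relevel(factor(d$measure), ref = "productivity")
            m <- lmerTest::lmer(
              coefficient ~ measure + (1 | species) + (1 | scheme),
              data = d, weights = 1 / se^2, REML = TRUE
            )
            co <- as.data.frame(summary(m)$coefficients)
            co$term <- rownames(co)
            write.csv(co, args[2], row.names = FALSE)
            write.csv(as.data.frame(VarCorr(m)), args[3], row.names = FALSE)
            """
        )
        subprocess.run(
            ["Rscript", "--vanilla", str(script), str(data_csv), str(fixed_csv), str(vc_csv)],
            check=True, capture_output=True, text=True,
        )
        oracle = pd.read_csv(fixed_csv).set_index("term")
        fit = fit_weighted_lmm(coef_table, model="A")

        for ours, theirs in (("(Intercept)", "(Intercept)"), ("measure[survival]", "measuresurvival")):
            got = fit[ours]
            assert got["estimate"] == pytest.approx(oracle.loc[theirs, "Estimate"], abs=1e-6)
            assert got["se"] == pytest.approx(oracle.loc[theirs, "Std. Error"], abs=1e-6)
            assert got["df"] == pytest.approx(oracle.loc[theirs, "df"], rel=1e-3)
            assert got["p"] == pytest.approx(oracle.loc[theirs, "Pr(>|t|)"], rel=1e-2, abs=1e-8)

        # variance components agree to the default lmer optimizer
        # tolerance; with a tightened bobyqa stop the two optima agree
        # to ~12 digits, so the residual gap is lmer's stopping rule
        vc = pd.read_csv(vc_csv).set_index("grp")["vcov"]
        assert fit.varcomps["species"] == pytest.approx(vc["species"], rel=5e-3, abs=1e-10)
        assert fit.varcomps["scheme"] == pytest.approx(vc["scheme"], rel=5e-3, abs=1e-10)
        assert fit.varcomps["residual"] == pytest.approx(vc["Residual"], rel=1e-4)


@pytest.fixture(scope="module")
def model_b_fit():
    table = simulate_coefficient_table(
        CoefficientTruth(intercept=0.05, survival_effect=0.02, temp_interaction=0.004),
        n_species=12, n_schemes=6, seed=3,
    )
    return fit_weighted_lmm(table, model="B")


class TestTemperaturePredictions:
    def test_predictions_follow_fitted_lines(self, model_b_fit):
        grid = np.array([8.0, 12.0, 16.0])
        pred = temperature_gradient_prediction(model_b_fit, grid)
        b = dict(zip(model_b_fit.result.fixed_names, model_b_fit.result.beta))
        surv = pred[pred["measure"] == "survival"].set_index("mean_temp_c")["predicted"]
        prod = pred[pred["measure"] == "productivity"].set_index("mean_temp_c")["predicted"]
        for t in grid:
            assert prod[t] == pytest.approx(b["(Intercept)"] + b["mean_temp"] * t, abs=1e-12)
            gap = surv[t] - prod[t]
            assert gap == pytest.approx(
                b["measure[survival]"] + b["measure[survival]:mean_temp"] * t, abs=1e-12
            )

    def test_interaction_sign_recovered(self, model_b_fit):
        term = model_b_fit["measure[survival]:mean_temp"]
        assert term["estimate"] == pytest.approx(0.004, abs=3 * term["se"])

    def test_extrapolation_warns(self, model_b_fit):
        with pytest.warns(UserWarning, match="beyond the observed range"):
            temperature_gradient_prediction(model_b_fit, [0.0, 30.0])

    def test_model_a_rejected(self, coef_table):
        fit = fit_weighted_lmm(coef_table, model="A")
        with pytest.raises(ValueError, match="model-B"):
            temperature_gradient_prediction(fit, [10.0])

    def test_within_range_no_warning(self, model_b_fit):
        lo, hi = model_b_fit.temp_range
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            temperature_gradient_prediction(model_b_fit, [lo, (lo + hi) / 2, hi])
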