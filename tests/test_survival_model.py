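"""The logistic survival GLMM: prediction, fitting, quadrature, Wald tests."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from scalesia_csm import (
    CohortConfig,
    SurvivalFit,
    SurvivalFixedEffects,
    SurvivalRandomEffects,
    fit_survival_glmm,
    glmm_loglik,
    predict_survival,
    survival_curve,
    wald_test,
)
from scalesia_csm.survival_model import _GlmmDesign, time_grid
from scalesia_csm.synthetic_cohort import generate_cohort_frame


class TestPredictSurvival:
    def test_reference_values_from_the_fitted_coefficients(self):
        fixed = SurvivalFixedEffects()
        assert predict_survival(fixed, "Control", 4.0) == pytest.approx(0.9412, abs=2e-4)
        assert predict_survival(fixed, "Cocoon", 0.0) == pytest.approx(0.9807, abs=2e-4)

    def test_strictly_decreasing_in_age(self):
        fixed = SurvivalFixedEffects()
        ages = np.linspace(0, 60, 200)
        p = predict_survival(fixed, "Waterboxx", ages)
        assert np.all(np.diff(p) < 0)
        assert p[-1] < 0.01

    def test_unknown_treatment_lists_valid_levels(self):
        with pytest.raises(ValueError, match="Cocoon"):
            predict_survival(SurvivalFixedEffects(), "Mulch", 1.0)

    def test_invariant_to_shifting_contrasts_into_the_intercept(self):
        fixed = SurvivalFixedEffects()
        shifted = SurvivalFixedEffects(
            intercept=fixed.intercept - 0.5,
            treatment_contrasts={k: v + 0.5 for k, v in fixed.treatment_contrasts.items()},
            age_slope=fixed.age_slope,
        )
        for treatment in fixed.treatment_contrasts:
            assert predict_survival(shifted, treatment, 3.0) == pytest.approx(
                predict_survival(fixed, treatment, 3.0), rel=1e-12
            )


class TestSurvivalCurve:
    def test_quarterly_grid_over_ten_years_has_41_points(self):
        curve = survival_curve(SurvivalFixedEffects(), "Control", horizon=10, step=0.25)
        assert len(curve) == 41
        assert curve["age"].iloc[-1] == 10.0

    def test_oversized_step_degrades_to_endpoints(self):
        curve = survival_curve(SurvivalFixedEffects(), "Control", horizon=2, step=5)
        assert list(curve["age"]) == [0.0, 2.0]

    def test_better_treatment_dominates_uniformly(self):
        fixed = SurvivalFixedEffects()
        better = survival_curve(fixed, "Cocoon+Hydrogel", 10, 0.25)["survival"]
        worse = survival_curve(fixed, "Control", 10, 0.25)["survival"]
        assert (better.to_numpy() > worse.to_numpy()).all()

    def test_time_grid_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            time_grid(0.0, 0.25)
        with pytest.raises(ValueError):
            time_grid(10.0, -1.0)


class TestFitAgainstOracles:
    def test_zero_variance_fit_matches_plain_logistic_regression(self):
        """Variances pinned at 0 reduce the GLMM to the GLM oracle exactly."""
        cfg = CohortConfig(n_plants=200, n_sites=4, seed=21)
        frame = generate_cohort_frame(cfg, None, None, SurvivalRandomEffects(0.0, 0.0))
        fit = fit_survival_glmm(frame, fixed_variances=(0.0, 0.0))
        design = _GlmmDesign(frame)
        glm = sm.GLM(design.y, design.X, family=sm.families.Binomial()).fit()
        assert np.abs(fit.estimates - np.asarray(glm.params)).max() < 1e-4

    def test_laplace_close_to_quadrature_on_a_small_instance(self):
        frame = generate_cohort_frame(CohortConfig(n_plants=30, n_sites=3, seed=5))
        fixed = SurvivalFixedEffects()
        random = SurvivalRandomEffects()
        ll_lap = glmm_loglik(frame, fixed, random, method="laplace")
        ll_agq = glmm_loglik(frame, fixed, random, method="agq", quad_nodes=15)
        assert abs(ll_lap - ll_agq) < 0.5

    def test_laplace_fit_agrees_with_lme4_glmer(self, tmp_path):
        """Independent oracle: R lme4 glmer (Laplace) on the same small data."""
        assert shutil.which("Rscript"), "Rscript is part of the supported toolchain"
        frame = generate_cohort_frame(CohortConfig(n_plants=80, n_sites=4, seed=11))
        fit = fit_survival_glmm(frame)
        csv = tmp_path / "records.csv"
        frame[["plant_id", "site_id", "treatment", "age", "alive"]].assign(
            alive=frame["alive"].astype(int)
        ).to_csv(csv, index=False)
        rcode = f"""
suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
d <- read.csv("{csv}")
d$treatment <- relevel(factor(d$treatment), ref="Cocoon")
m <- glmer(alive ~ treatment + age + (1|plant_id) + (1|site_id),
           data=d, family=binomial)
out <- list(fixef=as.list(fixef(m)),
            vc=as.list(unlist(lapply(VarCorr(m), function(x) as.numeric(x)))),
            ll=as.numeric(logLik(m)))
cat(toJSON(out, auto_unbox=TRUE))
"""
        res = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout)
        assert fit.fixed.age_slope == pytest.approx(ref["fixef"]["age"], abs=0.02)
        assert fit.fixed.intercept == pytest.approx(ref["fixef"]["(Intercept)"], abs=0.15)
        for level, value in ref["fixef"].items():
            name = level.removeprefix("treatment")
            if name in fit.fixed.treatment_contrasts and abs(value) < 5.0:
                assert fit.fixed.treatment_contrasts[name] == pytest.approx(
                    value, abs=0.2
                )
        assert fit.random.var_plant == pytest.approx(ref["vc"]["plant_id"], abs=0.15)
        assert fit.random.var_site == pytest.approx(ref["vc"]["site_id"], abs=0.15)
        assert fit.loglik == pytest.approx(ref["ll"], abs=0.5)


class TestFitBehaviour:
    def test_full_fit_converges_with_sane_estimates(self, small_fit):
        assert small_fit.converged
        assert small_fit.fixed.age_slope < 0
        assert small_fit.random.var_plant >= 0
        assert small_fit.random.var_site >= 0
        assert small_fit.n_plants == 120
        assert small_fit.n_sites == 4

    def test_all_alive_response_raises_separation_error(self, small_frame):
        frame = small_frame.copy()
        frame["alive"] = True
        frame["height"] = 100.0
        with pytest.raises(ValueError, match="separation"):
            fit_survival_glmm(frame)

    def test_single_treatment_level_raises_degenerate_design_error(self, small_frame):
        frame = small_frame.copy()
        frame["treatment"] = "Control"
        with pytest.raises(ValueError, match="degenerate design"):
            fit_survival_glmm(frame)

    def test_plants_in_two_sites_rejected(self, small_frame):
        frame = small_frame.copy()
        first_plant = frame["plant_id"].iloc[0]
        rows = frame.index[frame["plant_id"] == first_plant]
        frame.loc[rows[-1], "site_id"] = "S99"
        with pytest.raises(ValueError, match="nested"):
            fit_survival_glmm(pd.concat([frame, frame.tail(1)]))


class TestWald:
    def test_treatment_block_has_five_degrees_of_freedom(self, small_fit):
        result = wald_test(small_fit, "Treatment")
        assert result.df == 5
        assert result.chisq >= 0
        assert 0 <= result.p <= 1

    def test_single_df_term_equals_squared_z(self, small_fit):
        result = wald_test(small_fit, "Age")
        idx = small_fit.term_names.index("age")
        z = small_fit.estimates[idx] / np.sqrt(small_fit.vcov[idx, idx])
        assert result.df == 1
        assert result.chisq == pytest.approx(z**2, rel=1e-9)

    def test_zero_coefficients_with_identity_covariance_score_zero(self):
        terms = ["Intercept", "Cocoon+Hydrogel", "Control", "Hydrogel", "Waterboxx",
                 "Waterboxx+Hydrogel", "age"]
        fit = SurvivalFit(
            fixed=SurvivalFixedEffects(
                intercept=1.0,
                treatment_contrasts={t: 0.0 for t in ["Cocoon", *terms[1:-1]]},
                age_slope=-0.1,
            ),
            random=SurvivalRandomEffects(),
            vcov=np.eye(7),
            term_names=terms,
            loglik=0.0,
            n_obs=10,
            n_plants=5,
            n_sites=2,
            converged=True,
        )
        result = wald_test(fit, "Treatment")
        assert result.chisq == 0.0
        assert result.p == 1.0

    def test_singular_block_raises(self, small_fit):
        broken = SurvivalFit(
            fixed=small_fit.fixed,
            random=small_fit.random,
            vcov=np.zeros_like(small_fit.vcov),
            term_names=small_fit.term_names,
            loglik=small_fit.loglik,
            n_obs=small_fit.n_obs,
            n_plants=small_fit.n_plants,
            n_sites=small_fit.n_sites,
            converged=True,
        )
        with pytest.raises(ValueError, match="singular"):
            wald_test(broken, "Age")
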