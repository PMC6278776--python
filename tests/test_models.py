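"""Regression suite: fitting, prediction, residual standardisation."""

import numpy as np
import pandas as pd
import pytest

from somamosaic.models import (
    DEFAULT_SPECS,
    ModelSpec,
    RepeatRegression,
    attach_si_residual,
    expected_increment,
    standardize,
)


def linear_cohort(beta, n=60, noise_sd=0.0, seed=0, log_response=False):
    """Cohort drawn exactly from a known linear model."""
    rng = np.random.default_rng(seed)
    epal = rng.uniform(120, 800, n)
    age = rng.uniform(18, 65, n)
    eta = beta[0] + beta[1] * epal + beta[2] * age
    eta = eta + rng.normal(0, noise_sd, n)
    y = 10.0**eta if log_response else eta
    return pd.DataFrame(
        {"epal": epal, "age_at_sampling": age, "si": y},
        index=[f"S{i}" for i in range(n)],
    )


M8 = DEFAULT_SPECS["M8"]


class TestFit:
    def test_noiseless_recovery(self):
        beta = (0.8, 0.002, 0.01)
        data = linear_cohort(beta, log_response=True)
        fit = RepeatRegression(M8, data).fit()
        np.testing.assert_allclose(fit.params, beta, atol=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_permuted_response_r2_near_chance(self):
        # with the response permuted, E[R^2] = p/(n-1) under the null
        beta = (0.8, 0.002, 0.01)
        data = linear_cohort(beta, noise_sd=0.05, log_response=True, n=41)
        rng = np.random.default_rng(1)
        r2 = []
        for _ in range(300):
            shuffled = data.copy()
            shuffled["si"] = rng.permutation(shuffled["si"].to_numpy())
            r2.append(RepeatRegression(M8, shuffled).fit().r_squared)
        assert np.mean(r2) == pytest.approx(2 / 40, abs=0.02)

    def test_rank_deficient_design_raises(self):
        data = linear_cohort((0.8, 0.002, 0.01), log_response=True)
        data["age_at_sampling"] = 2.0 * data["epal"]
        with pytest.raises(ValueError, match="rank deficient"):
            RepeatRegression(M8, data).fit()

    def test_nonpositive_log_response_names_subjects(self):
        data = linear_cohort((0.8, 0.002, 0.01), log_response=True)
        data.loc["S3", "si"] = -1.0
        with pytest.raises(ValueError, match="S3"):
            RepeatRegression(M8, data)

    def test_too_few_rows(self):
        data = linear_cohort((0.8, 0.002, 0.01), n=3, log_response=True)
        with pytest.raises(ValueError, match="at least"):
            RepeatRegression(M8, data)


class TestResiduals:
    def test_standardized_contract(self):
        data = linear_cohort((0.8, 0.002, 0.01), noise_sd=0.1,
                             log_response=True)
        fit = RepeatRegression(M8, data).fit()
        assert fit.std_residuals.mean() == pytest.approx(0.0, abs=1e-9)
        assert fit.std_residuals.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_affine_predictor_invariance(self):
        data = linear_cohort((0.8, 0.002, 0.01), noise_sd=0.1,
                             log_response=True)
        fit = RepeatRegression(M8, data).fit()
        scaled = data.copy()
        scaled["epal"] = scaled["epal"] * 1000 + 5.0
        fit2 = RepeatRegression(M8, scaled).fit()
        np.testing.assert_allclose(
            fit.std_residuals, fit2.std_residuals, atol=1e-8
        )

    def test_attach_residual(self):
        data = linear_cohort((0.8, 0.002, 0.01), noise_sd=0.1,
                             log_response=True)
        fit = RepeatRegression(M8, data).fit()
        out = attach_si_residual(data, fit)
        assert out["si_residual"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["si_residual"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        # residual ranks equal observed-minus-expected ranks
        diff = np.log10(data["si"]) - np.log10(fit.predict(data))
        assert (out["si_residual"].rank() == diff.rank()).all()

    def test_residual_definition(self):
        # residual = observed - predicted on the transformed scale, so a
        # subject sitting exactly on the regression line has residual 0
        data = linear_cohort((0.8, 0.002, 0.01), noise_sd=0.1,
                             log_response=True)
        fit = RepeatRegression(M8, data).fit()
        manual = np.log10(data["si"]) - np.log10(fit.predict(data))
        np.testing.assert_allclose(fit.residuals, manual, atol=1e-10)
        on_line = linear_cohort((0.8, 0.002, 0.01), log_response=True)
        fit2 = RepeatRegression(M8, on_line).fit()
        np.testing.assert_allclose(fit2.residuals, 0.0, atol=1e-8)

    def test_attach_missing_subject_raises(self):
        data = linear_cohort((0.8, 0.002, 0.01), noise_sd=0.1,
                             log_response=True)
        fit = RepeatRegression(M8, data.iloc[:-5], ).fit()
        with pytest.raises(ValueError, match="missing"):
            attach_si_residual(data, fit)


class TestPredict:
    def test_dot_product_oracle(self):
        data = linear_cohort((0.8, 0.002, 0.01), noise_sd=0.1,
                             log_response=True)
        fit = RepeatRegression(M8, data).fit()
        rng = np.random.default_rng(5)
        subjects = pd.DataFrame(
            {
                "epal": rng.uniform(120, 800, 10),
                "age_at_sampling": rng.uniform(18, 65, 10),
            }
        )
        manual = 10.0 ** (
            fit.params[0]
            + fit.params[1] * subjects["epal"]
            + fit.params[2] * subjects["age_at_sampling"]
        )
        np.testing.assert_allclose(fit.predict(subjects), manual, rtol=1e-12)

    def test_missing_predictor_raises(self):
        data = linear_cohort((0.8, 0.002, 0.01), log_response=True)
        fit = RepeatRegression(M8, data).fit()
        with pytest.raises(ValueError, match="lack predictors"):
            fit.predict(pd.DataFrame({"epal": [300.0]}))

    def test_fixed_coefficients_closed_form(self):
        spec = ModelSpec(
            "M8", "si", "log10",
            (("epal", "identity"), ("age_at_sampling", "identity")),
            fixed_coefficients=(1.0, 0.001, 0.005),
        )
        data = linear_cohort((1.0, 0.001, 0.005), log_response=True)
        fit = RepeatRegression(spec, data).fit()
        np.testing.assert_allclose(fit.params, (1.0, 0.001, 0.005))
        assert fit.r_squared == pytest.approx(1.0)
        pred = fit.predict(pd.DataFrame(
            {"epal": [400.0], "age_at_sampling": [50.0]}
        ))
        assert pred.iloc[0] == pytest.approx(10 ** (1.0 + 0.4 + 0.25))


class TestExpectedIncrement:
    def test_zero_coefficients(self):
        spec = ModelSpec(
            "INCR", "observed_increment", "identity",
            (("mode", "identity"), ("interval", "identity")),
            fixed_coefficients=(0.0, 0.0, 0.0),
        )
        assert expected_increment(spec, 700, 10) == 0.0

    def test_arithmetic(self):
        spec = ModelSpec(
            "INCR", "observed_increment", "identity",
            (("mode", "identity"), ("interval", "identity")),
            fixed_coefficients=(0.0, 0.05, 10.0),
        )
        assert expected_increment(spec, 400, 4) == pytest.approx(60.0)

    def test_refit_recovers_generating_values(self):
        rng = np.random.default_rng(9)
        beta = (5.0, 0.04, 8.0)
        mode = rng.uniform(150, 800, 120)
        interval = rng.uniform(2, 11, 120)
        y = beta[0] + beta[1] * mode + beta[2] * interval + rng.normal(0, 3, 120)
        data = pd.DataFrame(
            {"observed_increment": y, "mode": mode, "interval": interval}
        )
        fit = RepeatRegression(DEFAULT_SPECS["INCR"], data).fit()
        np.testing.assert_allclose(fit.params, beta, rtol=0.15)
        assert expected_increment(fit, 400.0, 4.0) == pytest.approx(
            fit.params[0] + fit.params[1] * 400 + fit.params[2] * 4
        )

    def test_requires_coefficients(self):
        with pytest.raises(ValueError, match="fitted model or fixed"):
            expected_increment(DEFAULT_SPECS["INCR"], 400, 4)


class TestSuiteStructure:
    def test_m11_extends_m10(self):
        m10, m11 = DEFAULT_SPECS["M10"], DEFAULT_SPECS["M11"]
        assert set(m10.predictors) < set(m11.predictors)
        extra = set(m11.predictors) - set(m10.predictors)
        assert extra == {("si_residual", "identity")}

    def test_m11_r2_at_least_m10(self):
        rng = np.random.default_rng(3)
        n = 80
        data = pd.DataFrame(
            {
                "epal": rng.uniform(120, 800, n),
                "age_at_onset": rng.uniform(10, 60, n),
                "si_residual": standardize(rng.normal(size=n)),
            },
            index=[f"S{i}" for i in range(n)],
        )
        r10 = RepeatRegression(DEFAULT_SPECS["M10"], data).fit().r_squared
        r11 = RepeatRegression(DEFAULT_SPECS["M11"], data).fit().r_squared
        assert r11 >= r10


def test_standardize_constant_raises():
    with pytest.raises(ValueError, match="constant"):
        standardize(np.ones(5))
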