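"""Transform selection, prior arithmetic, likelihoods, and model fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from partikel.models import (
    ContrastCoding,
    MarginalHierarchicalModel,
    ModelError,
    PriorSpec,
    design_matrix_2x2,
    fit_hurdle_entropy,
    fit_reading_model,
    fit_zoib_cloze,
    hurdle_lognormal_log_density,
    prior_predictive_bounds,
    select_boxcox_lambda,
    zoib_log_density,
)
from partikel.synthetic import ExperimentDesign, GenerativeParams, generate_spr_trials


class TestBoxCox:
    def test_reciprocal_data_selects_lambda_near_minus_one(self):
        rng = np.random.default_rng(1)
        speed = rng.normal(2.5, 0.1, 800)
        y = 1000.0 / speed
        lam, profile = select_boxcox_lambda(y)
        assert -1.3 <= lam <= -0.7
        assert profile["loglik"].idxmax() == profile["lambda"].tolist().index(lam)

    def test_lognormal_data_selects_lambda_near_zero(self):
        rng = np.random.default_rng(2)
        y = np.exp(rng.normal(5.7, 0.4, 800))
        lam, _ = select_boxcox_lambda(y)
        assert -0.3 <= lam <= 0.3

    def test_gaussian_data_selects_identity(self):
        # spread must be large enough to constrain lambda: at coefficient of
        # variation ~0.03 the profile is nearly flat and the argmax drifts
        rng = np.random.default_rng(3)
        y = rng.normal(300, 60, 800)
        lam, _ = select_boxcox_lambda(y)
        assert 0.7 <= lam <= 1.3

    def test_nonpositive_values_direct_to_exclusion(self):
        with pytest.raises(ModelError, match="exclusion"):
            select_boxcox_lambda([3.0, -1.0, 2.0])


class TestPriorPredictiveBounds:
    def test_log_scale_reading_time_window(self):
        b = prior_predictive_bounds(PriorSpec.eye_tracking(), "log_ms", 2.0)
        assert (b.response_low, b.response_high) == (110, 812)
        assert b.effect_slowdown == 513
        # exp(5.7) - exp(4.7) = 188.9 ms, a hair under the 190 anchor
        assert abs(b.effect_speedup - 190) <= 1

    def test_reciprocal_scale_speed_window(self):
        b = prior_predictive_bounds(
            PriorSpec.self_paced_reading(), "reciprocal_speed", 2.0
        )
        assert (b.response_low, b.response_high) == (2, 4)

    def test_zero_sd_window_degenerates_to_mean(self):
        b = prior_predictive_bounds(PriorSpec.eye_tracking(), "log_ms", 0.0)
        assert b.response_low == b.response_high == b.prior_mean_response


class TestContrasts:
    def test_codes_must_sum_to_zero(self):
        with pytest.raises(ModelError):
            ContrastCoding(set_size={"small": 0.0, "large": 1.0})

    def test_design_matrix_columns(self):
        df = pd.DataFrame(
            {"set_size": ["small", "large"], "distance": ["short", "long"]}
        )
        X = design_matrix_2x2(df)
        assert np.allclose(X, [[1, -0.5, -0.5, 0.25], [1, 0.5, 0.5, 0.25]])


class TestMarginalLikelihoodAlgebra:
    def test_marginal_gaussian_matches_dense_mvn(self):
        """Woodbury/capacitance shortcut equals the brute-force MVN logpdf."""
        rng = np.random.default_rng(8)
        n_part, n_item, n = 6, 4, 48
        part = np.repeat(np.arange(n_part), n // n_part)
        item = np.tile(np.arange(n_item), n // n_item)
        X = np.column_stack([np.ones(n), rng.choice([-0.5, 0.5], n)])
        y = rng.normal(2.5, 0.6, n)
        model = MarginalHierarchicalModel(
            y, X, part, item, PriorSpec.self_paced_reading(),
            random_structure="intercepts",
        )
        theta = np.array([[2.4, 0.1, np.log(0.3), np.log(0.15), np.log(0.5)]])
        got = model.log_likelihood_batch(theta)[0]

        Zp = np.eye(n_part)[part]
        Zi = np.eye(n_item)[item]
        cov = (
            0.5**2 * np.eye(n)
            + 0.3**2 * Zp @ Zp.T
            + 0.15**2 * Zi @ Zi.T
        )
        want = stats.multivariate_normal.logpdf(
            y, mean=X @ np.array([2.4, 0.1]), cov=cov
        )
        assert got == pytest.approx(want, rel=1e-10)

    def test_conjugate_normal_special_case(self):
        """With no random effects and a fixed-variance-dominated posterior,
        the intercept posterior matches the conjugate closed form."""
        rng = np.random.default_rng(21)
        sigma_true = 0.4
        y = rng.normal(2.8, sigma_true, 300)
        trials = pd.DataFrame(
            {
                "participant": ["p1"] * 300,
                "item": ["i1"] * 300,
                "set_size": ["small", "large"] * 150,
                "distance": ["short", "long"] * 150,
                "rt_ms": 1000.0 / y,
            }
        )
        prior = PriorSpec.self_paced_reading()
        fit = fit_reading_model(
            trials, ContrastCoding(), prior, "reciprocal_speed",
            random_structure="none", seed=3, n_warmup=400, n_steps=400,
        )
        post_var = 1.0 / (1 / prior.intercept_scale**2
                          + len(y) / sigma_true**2)
        post_mean = post_var * (
            prior.intercept_loc / prior.intercept_scale**2
            + y.sum() / sigma_true**2
        )
        got = fit.params.set_index("parameter").loc["intercept", "mean"]
        assert got == pytest.approx(post_mean, abs=3 * np.sqrt(post_var))
        assert abs(got - post_mean) < 0.02

    def test_degenerate_single_participant_rejected(self):
        trials = pd.DataFrame(
            {
                "participant": ["p1"] * 12,
                "item": ["i1"] * 12,
                "set_size": ["small", "large"] * 6,
                "distance": ["short", "long"] * 6,
                "rt_ms": np.linspace(300, 500, 12),
            }
        )
        with pytest.raises(ModelError, match="participants"):
            fit_reading_model(
                trials, ContrastCoding(), PriorSpec.self_paced_reading(),
                "reciprocal_speed", seed=1,
            )


class TestReadingModelFits:
    def test_contrast_sign_flip_flips_slope_posterior(self, small_design):
        params = GenerativeParams.spr_defaults(
            effect_set_size=0.3, sub100_fraction=0.0, seed=31
        )
        trials = generate_spr_trials(small_design, params)
        prior = PriorSpec.self_paced_reading()
        fit_a = fit_reading_model(
            trials, ContrastCoding(), prior, "reciprocal_speed", seed=4,
            n_warmup=300, n_steps=300,
        )
        flipped = ContrastCoding(
            set_size={"small": 0.5, "large": -0.5},
            distance={"short": 0.5, "long": -0.5},
        )
        fit_b = fit_reading_model(
            trials, flipped, prior, "reciprocal_speed", seed=4,
            n_warmup=300, n_steps=300,
        )
        a = fit_a.params.set_index("parameter").loc["set_size", "mean"]
        b = fit_b.params.set_index("parameter").loc["set_size", "mean"]
        assert a == pytest.approx(-b, abs=0.03)
        assert a > 0

    def test_planted_entropy_slope_detected_at_paper_scale(self, paper_design):
        params = GenerativeParams.et_defaults(
            entropy_as_predictor=True, entropy_slope=0.12, seed=33
        )
        from partikel.synthetic import generate_et_trials

        trials = generate_et_trials(paper_design, params)
        fit = fit_reading_model(
            trials, ContrastCoding(), PriorSpec.eye_tracking(), "log_ms",
            predictors="entropy", response_column="ffd_ms", seed=5,
            n_warmup=400, n_steps=400,
        )
        row = fit.params.set_index("parameter").loc["entropy"]
        assert row["ci_low"] > 0
        assert row["ci_low"] < 0.12 < row["ci_high"]

    def test_random_slopes_structure_runs_and_recovers_intercept(
        self, small_design
    ):
        params = GenerativeParams.spr_defaults(sub100_fraction=0.0, seed=35)
        trials = generate_spr_trials(small_design, params)
        fit = fit_reading_model(
            trials, ContrastCoding(), PriorSpec.self_paced_reading(),
            "reciprocal_speed", random_structure="slopes", seed=6,
            n_warmup=400, n_steps=400,
        )
        row = fit.params.set_index("parameter").loc["intercept"]
        assert row["ci_low"] < 2.5 < row["ci_high"]
        assert {"sd_participant_set_size", "sd_item_distance"} <= set(
            fit.params["parameter"]
        )


class TestZOIB:
    def test_reduces_to_beta_when_no_inflation(self):
        val = zoib_log_density(np.array([0.5]), 0.0, 0.5, np.array([0.5]), 4.0)
        assert np.exp(val[0]) == pytest.approx(1.5, rel=1e-12)
        assert np.exp(val[0]) == pytest.approx(
            stats.beta(2, 2).pdf(0.5), rel=1e-12
        )

    def test_total_probability_is_one_by_quadrature(self):
        for alpha, g1, mu, phi in [(0.2, 0.5, 0.6, 4.0), (0.05, 0.9, 0.3, 12.0)]:
            cont, _ = integrate.quad(
                lambda y: float(np.exp(
                    zoib_log_density(np.array([y]), alpha, g1,
                                     np.array([mu]), phi)
                )[0]), 0, 1,
            )
            total = alpha * (1 - g1) + alpha * g1 + cont
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_parameter_recovery_within_credible_intervals(self):
        rng = np.random.default_rng(41)
        n = 240
        c1 = rng.choice([-0.5, 0.5], n)
        X = np.column_stack([np.ones(n), c1])
        mu = special.expit(special.logit(0.6) + 0.0 * c1)
        y = rng.beta(mu * 6, (1 - mu) * 6)
        boundary = rng.random(n) < 0.2
        y[boundary] = (rng.random(int(boundary.sum())) < 0.5).astype(float)
        fit = fit_zoib_cloze(y, X, slope_names=("set_size",), seed=7)
        p = fit.params.set_index("parameter")
        assert p.loc["alpha", "ci_low"] < 0.2 < p.loc["alpha", "ci_high"]
        assert p.loc["gamma1", "ci_low"] < 0.5 < p.loc["gamma1", "ci_high"]
        mu_mean = special.expit(p.loc["intercept", "mean"])
        assert mu_mean == pytest.approx(0.6, abs=0.07)

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ModelError):
            fit_zoib_cloze(np.array([0.5, 1.2]), np.ones((2, 1)))


class TestHurdleLognormal:
    def test_reduces_to_lognormal_without_hurdle(self):
        y = np.array([1.3])
        got = hurdle_lognormal_log_density(y, 0.0, np.array([0.2]), 0.5)
        want = stats.lognorm(s=0.5, scale=np.exp(0.2)).logpdf(1.3)
        assert got[0] == pytest.approx(want, rel=1e-12)

    def test_total_probability_is_one_by_quadrature(self):
        for th, m, s in [(0.1, 0.2, 0.5), (0.4, -0.1, 0.3)]:
            cont, _ = integrate.quad(
                lambda y: float(np.exp(
                    hurdle_lognormal_log_density(np.array([y]), th,
                                                 np.array([m]), s)
                )[0]), 0, np.inf,
            )
            assert th + cont == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_input_concentrates_hurdle_near_one(self):
        y = np.zeros(40)
        X = np.ones((40, 1))
        fit = fit_hurdle_entropy(y, X, slope_names=(), seed=8,
                                 n_warmup=400, n_steps=400)
        p = fit.params.set_index("parameter")
        assert p.loc["theta0", "mean"] > 0.9

    def test_tight_default_slope_prior_shrinks_hard(self):
        # generating slope 0.3 on the log scale; the Normal(0, 0.01) prior
        # pins the posterior near zero — printed-prior behaviour, documented
        rng = np.random.default_rng(43)
        n = 200
        c1 = rng.choice([-0.5, 0.5], n)
        X = np.column_stack([np.ones(n), c1])
        y = np.exp(rng.normal(0.1 + 0.3 * c1, 0.3))
        y[rng.random(n) < 0.05] = 0.0
        tight = fit_hurdle_entropy(y, X, slope_names=("set_size",), seed=9)
        wide = fit_hurdle_entropy(y, X, slope_names=("set_size",),
                                  slope_scale=0.5, seed=9)
        t = tight.params.set_index("parameter").loc["set_size", "mean"]
        w = wide.params.set_index("parameter").loc["set_size", "mean"]
        assert abs(t) < 0.05
        assert w == pytest.approx(0.3, abs=0.1)

    def test_negative_values_rejected(self):
        with pytest.raises(ModelError):
            fit_hurdle_entropy(np.array([0.2, -0.1]), np.ones((2, 1)))
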