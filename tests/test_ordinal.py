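"""Cumulative-logit machinery: scaling, priors, derived quantities."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from metacog import cohort, ordinal
from metacog.ordinal import (
    MCMCConfig,
    OrdinalFit,
    OrdinalModelSpec,
    ScalingRecord,
    category_probabilities,
    fit_ordinal,
    marginal_effects,
    odds_ratio,
    pseudo_r2,
    scale_predictors,
)

TINY_MCMC = MCMCConfig(chains=2, samples=400, burn=300, thin=1, seed=3)


class TestScaling:
    def test_two_sd_formula(self):
        df = pd.DataFrame({"x": [5 - 2, 5 + 2, 5 - 2, 5 + 2, 9.0]})
        scaled, rec = scale_predictors(df, ["x"])
        m, s = rec.stats["x"]
        assert scaled.loc[4, "x"] == pytest.approx((9 - m) / (2 * s))

    def test_scaled_column_has_half_sd(self, rng):
        df = pd.DataFrame({"x": rng.normal(3, 7, 500)})
        scaled, _ = scale_predictors(df, ["x"])
        assert scaled["x"].std(ddof=1) == pytest.approx(0.5, abs=1e-12)

    def test_rescaling_standardised_input_is_stable(self, rng):
        df = pd.DataFrame({"x": rng.normal(0, 0.5, 500)})
        once, _ = scale_predictors(df, ["x"])
        twice, _ = scale_predictors(once, ["x"])
        assert np.allclose(once["x"], twice["x"] * once["x"].std(ddof=1) / 0.5,
                           atol=1e-9)

    def test_zero_sd_names_column(self):
        with pytest.raises(ValueError, match="const"):
            scale_predictors(pd.DataFrame({"const": [1.0] * 5}), ["const"])


class TestCategoryProbabilities:
    def test_sum_to_one(self, rng):
        kappa = np.sort(rng.normal(0, 1, 3))
        eta = rng.normal(0, 2, 50)
        p = category_probabilities(kappa, eta)
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(p >= 0)

    def test_likelihood_invariant_to_joint_shift(self, rng):
        """Adding a constant to eta and every cut point changes nothing."""
        kappa = np.array([-1.0, 0.2, 1.4])
        eta = rng.normal(0, 1, 20)
        shift = 2.7
        assert np.allclose(category_probabilities(kappa, eta),
                           category_probabilities(kappa + shift, eta + shift))


class TestKappaPrior:
    def test_flat_dirichlet_pushforward(self):
        """The induced density is the Jacobian of the logistic transform."""
        kappa = np.array([-0.8, 0.1, 1.1])
        q = expit(kappa)
        expected = np.sum(np.log(q) + np.log1p(-q))
        assert ordinal._kappa_logprior(kappa) == pytest.approx(expected)

    def test_misordered_cutpoints_excluded(self):
        assert ordinal._kappa_logprior(np.array([0.5, -0.5])) == -np.inf


def make_fake_fit(beta_draws, kappa_draws, scaling=None, taus=None,
                  eta_var=None, names=("x",)):
    draws = {"beta": beta_draws, "kappa": kappa_draws}
    group_levels = {}
    if taus:
        for g, arr in taus.items():
            draws[f"tau_{g}"] = arr
            group_levels[g] = ["a", "b"]
    nchain, nd = beta_draws.shape[:2]
    return OrdinalFit(
        spec=OrdinalModelSpec(outcome="y", categories=("a", "b", "c"),
                              fixed_effects=names, mcmc=TINY_MCMC),
        draws=draws, feature_names=tuple(names), group_levels=group_levels,
        scaling=scaling or ScalingRecord(stats={}),
        eta_var=np.zeros((nchain, nd)) if eta_var is None else eta_var,
    )


class TestOddsRatio:
    def test_zero_slope_gives_unit_or(self):
        fit = make_fake_fit(np.zeros((1, 100, 1)), np.zeros((1, 100, 2)))
        assert odds_ratio(fit, "x", per="1sd")["mean"] == pytest.approx(1.0)
        assert odds_ratio(fit, "x", per="2sd")["mean"] == pytest.approx(1.0)

    def test_two_sd_slope_halves_on_one_sd_scale(self):
        b = np.full((1, 100, 1), np.log(4.0))
        fit = make_fake_fit(b, np.zeros((1, 100, 2)))
        assert odds_ratio(fit, "x", per="1sd")["mean"] == pytest.approx(2.0)
        assert odds_ratio(fit, "x", per="2sd")["mean"] == pytest.approx(4.0)

    def test_unknown_predictor_raises(self):
        fit = make_fake_fit(np.zeros((1, 10, 1)), np.zeros((1, 10, 2)))
        with pytest.raises(LookupError):
            odds_ratio(fit, "nope")


class TestMarginalEffects:
    def make_fit(self, beta_value, rng):
        b = np.full((1, 200, 1), beta_value) + rng.normal(0, 1e-6, (1, 200, 1))
        k = np.tile(np.array([-0.5, 0.8]), (1, 200, 1))
        scaling = ScalingRecord(stats={"x": (0.0, 0.5)})
        return make_fake_fit(b, k, scaling=scaling)

    def test_probabilities_sum_to_one(self, rng):
        fit = self.make_fit(-0.6, rng)
        me = marginal_effects(fit, "x", np.linspace(0.5, 1.5, 7))
        assert np.allclose(me["mean"].sum(axis=-1), 1.0, atol=1e-10)

    def test_negative_slope_monotone_lowest_category(self, rng):
        fit = self.make_fit(-0.9, rng)
        me = marginal_effects(fit, "x", np.linspace(0.5, 2.0, 9))
        lowest = me["mean"][:, 0]
        assert np.all(np.diff(lowest) > 0)   # prob of lowest category rises

    def test_matches_closed_form(self, rng):
        fit = self.make_fit(0.7, rng)
        grid = np.array([0.8, 1.2])
        me = marginal_effects(fit, "x", grid)
        b = fit.flat("beta")[:, 0]
        kappa = fit.flat("kappa")
        x = (np.log(grid) - 0.0) / (2 * 0.5)
        eta = b[:, None] * x[None, :]
        cum = expit(kappa[:, None, :] - eta[..., None])
        probs = np.diff(np.concatenate([cum, np.ones(cum.shape[:2] + (1,))],
                                       axis=-1), axis=-1, prepend=0.0)
        assert np.allclose(me["draws"], probs, atol=1e-6)

    def test_unscaled_predictor_rejected(self, rng):
        fit = self.make_fit(0.1, rng)
        with pytest.raises(ValueError):
            marginal_effects(fit, "unknown", np.array([1.0]))


class TestPseudoR2:
    def test_null_model_is_zero(self):
        fit = make_fake_fit(np.zeros((1, 50, 0)), np.zeros((1, 50, 2)),
                            names=())
        assert pseudo_r2(fit) == pytest.approx(0.0)

    def test_dominant_fixed_variance_approaches_one(self):
        fit = make_fake_fit(np.zeros((1, 50, 1)), np.zeros((1, 50, 2)),
                            eta_var=np.full((1, 50), 1e8))
        assert pseudo_r2(fit) == pytest.approx(1.0, abs=1e-6)

    def test_random_intercept_variance_counts_as_unexplained(self):
        tau = np.full((1, 50), 2.0)
        fit = make_fake_fit(np.zeros((1, 50, 1)), np.zeros((1, 50, 2)),
                            taus={"g": tau}, eta_var=np.full((1, 50), 1.0))
        expected = 1.0 / (1.0 + 4.0 + np.pi ** 2 / 3)
        assert pseudo_r2(fit) == pytest.approx(expected)


class TestFitOrdinal:
    @pytest.fixture(scope="class")
    def fitted(self):
        am = cohort.AttitudeModelConfig(
            beta={"log_mratio": 1.0, "age": 0.3},
            groups={"region": (4, 0.4)})
        cfg = cohort.CohortConfig(n_subjects=500, attitude_model=am, seed=21)
        _, att, gt = cohort.generate_cohort(cfg)
        data = att.df.merge(
            gt.subjects[["respondent_id", "log_mratio_covid"]],
            on="respondent_id").rename(columns={"log_mratio_covid": "log_mratio"})
        spec = OrdinalModelSpec(
            outcome="vaccine_intent", categories=am.categories,
            fixed_effects=("log_mratio", "age"), scale_2sd=("log_mratio", "age"),
            random_groups=("region",), mcmc=TINY_MCMC)
        return spec, data, fit_ordinal(spec, data)

    def test_slope_sign_recovered(self, fitted):
        _, _, fit = fitted
        assert fit.beta_draws("log_mratio").mean() > 0

    def test_cutpoints_ascending_in_every_draw(self, fitted):
        _, _, fit = fitted
        kappa = fit.flat("kappa")
        assert np.all(np.diff(kappa, axis=-1) > 0)

    def test_same_seed_reproduces_draws(self, fitted):
        spec, data, fit = fitted
        fit2 = fit_ordinal(spec, data)
        assert np.array_equal(fit.flat("beta"), fit2.flat("beta"))

    def test_extra_covariate_is_just_one_more_column(self, fitted):
        """The science-domain control model reuses the same fit path."""
        spec, data, _ = fitted
        data = data.assign(extra=np.linspace(-1, 1, len(data)))
        spec2 = dataclasses.replace(
            spec, fixed_effects=spec.fixed_effects + ("extra",),
            scale_2sd=spec.scale_2sd + ("extra",))
        fit2 = fit_ordinal(spec2, data)
        assert fit2.flat("beta").shape[-1] == 3

    def test_undeclared_category_rejected(self, fitted):
        spec, data, _ = fitted
        bad = data.copy()
        bad.loc[bad.index[0], "vaccine_intent"] = "whenever"
        with pytest.raises(ValueError):
            fit_ordinal(spec, bad)
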