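"""State-space model: joint density, sampler contracts, diagnostics, priors."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from eiderpva import (
    MCMCSettings,
    ModelSpec,
    PosteriorDraws,
    PriorSpec,
    SurveyObservation,
    SurveySeries,
    builtin_series,
    default_model_spec,
    derive_observer_prior,
    gamma_moment_match,
    gelman_rubin,
    log_joint_density,
    prior_vcf_deviation_quantiles,
    sample_posterior,
    summarize,
)
from eiderpva.ssm import CONSTANT_DETECTION, LATENT_VCF, LATENT_VCF_OBSERVER

from conftest import SMOKE


def toy_series(values=((2007, 1000.0, 50.0), (2008, 1100.0, 60.0), (2009, 1250.0, 70.0))):
    return SurveySeries("toy", tuple(SurveyObservation(y, e, s) for y, e, s in values))


INFORMATIVE = PriorSpec(logN0_mean=6.9, logN0_sd=0.1, rbar_mean=0.0, rbar_sd=0.1,
                        sigma_r_shape=3.0, sigma_r_rate=20.0)


class TestModelSpecs:
    def test_acp1_priors_and_variant(self):
        spec, series = default_model_spec("ACP1")
        assert spec.variant == CONSTANT_DETECTION
        assert (spec.priors.logN0_mean, spec.priors.logN0_sd) == (8.78, 0.1)
        assert (spec.priors.rbar_mean, spec.priors.rbar_sd) == (0.0, 0.1)
        assert (spec.priors.sigma_r_shape, spec.priors.sigma_r_rate) == (3.0, 20.0)
        assert series.population == "ACP"

    def test_ykd2_is_diffuse(self):
        spec, _ = default_model_spec("YKD2")
        assert (spec.priors.logN0_mean, spec.priors.logN0_sd) == (9.43, 0.5)
        assert spec.priors.rbar_sd == 0.5
        assert (spec.priors.sigma_r_shape, spec.priors.sigma_r_rate) == (3.0, 2.0)

    def test_ykd3_masks_2015(self):
        _, series = default_model_spec("YKD3")
        assert not series.observation(2015).observed
        assert series.n_observed == 11  # 2011 gap plus the masked 2015

    def test_ykd4_observer_configuration(self):
        spec, series = default_model_spec("YKD4")
        assert spec.variant == LATENT_VCF_OBSERVER
        assert spec.observer_year == 2015
        assert (spec.priors.sigma_d_shape, spec.priors.sigma_d_rate) == (1.0, 10.0)
        assert (spec.priors.beta_shape, spec.priors.beta_rate) == (15.5, 9.0)
        assert series.n_observed == 12

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            default_model_spec("YKD9")

    def test_prior_variant_consistency_enforced(self):
        with pytest.raises(ValueError):
            ModelSpec(LATENT_VCF, INFORMATIVE)  # no sigma_d prior
        with pytest.raises(ValueError):
            ModelSpec(CONSTANT_DETECTION, INFORMATIVE, observer_year=2015)


class TestLogJointDensity:
    def test_matches_term_by_term_oracle(self):
        """Full density equals an independent scipy computation to 1e-10."""
        series = toy_series()
        spec = ModelSpec(CONSTANT_DETECTION, INFORMATIVE)
        logn = np.array([6.95, 7.02, 7.10])
        state = {"logn": logn, "rbar": 0.03, "sigma_r": 0.12}
        expected = (
            stats.norm.logpdf(logn[0], 6.9, 0.1)
            + stats.norm.logpdf(0.03, 0.0, 0.1)
            + stats.gamma.logpdf(0.12, 3.0, scale=1 / 20.0)
            + stats.norm.logpdf(logn[1] - logn[0], 0.03, 0.12)
            + stats.norm.logpdf(logn[2] - logn[1], 0.03, 0.12)
            + stats.norm.logpdf(1000.0, math.exp(logn[0]), 50.0)
            + stats.norm.logpdf(1100.0, math.exp(logn[1]), 60.0)
            + stats.norm.logpdf(1250.0, math.exp(logn[2]), 70.0)
        )
        assert log_joint_density(spec, series, state) == pytest.approx(expected, abs=1e-10)

    def test_latent_variant_matches_oracle(self):
        series = toy_series()
        priors = PriorSpec(logN0_mean=6.9, logN0_sd=0.1, rbar_mean=0.0, rbar_sd=0.1,
                           sigma_r_shape=3.0, sigma_r_rate=20.0,
                           sigma_d_shape=1.0, sigma_d_rate=10.0)
        spec = ModelSpec(LATENT_VCF, priors)
        logn = np.array([6.95, 7.02, 7.10])
        logd = np.array([0.02, -0.05, 0.01])
        state = {"logn": logn, "rbar": 0.03, "sigma_r": 0.12,
                 "logd": logd, "sigma_d": 0.05}
        expected = (
            stats.norm.logpdf(logn[0], 6.9, 0.1)
            + stats.norm.logpdf(0.03, 0.0, 0.1)
            + stats.gamma.logpdf(0.12, 3.0, scale=1 / 20.0)
            + stats.norm.logpdf(np.diff(logn), 0.03, 0.12).sum()
            + stats.gamma.logpdf(0.05, 1.0, scale=1 / 10.0)
            + stats.norm.logpdf(logd, 0.0, 0.05).sum()
            + stats.norm.logpdf([1000.0, 1100.0, 1250.0],
                                np.exp(logn - logd), [50.0, 60.0, 70.0]).sum()
        )
        assert log_joint_density(spec, series, state) == pytest.approx(expected, abs=1e-10)

    def test_missing_year_contributes_only_transition_terms(self):
        """Shifting a missing-survey year's latent abundance changes the
        density only through the two adjacent growth increments."""
        series = SurveySeries("gap", (
            SurveyObservation(2007, 1000.0, 50.0),
            SurveyObservation.missing(2008),
            SurveyObservation(2009, 1250.0, 70.0),
        ))
        spec = ModelSpec(CONSTANT_DETECTION, INFORMATIVE)
        base = {"logn": np.array([6.95, 7.02, 7.10]), "rbar": 0.03, "sigma_r": 0.12}
        bumped = {**base, "logn": base["logn"] + np.array([0.0, 0.08, 0.0])}
        delta = log_joint_density(spec, series, bumped) - log_joint_density(spec, series, base)
        expected = (
            stats.norm.logpdf(np.diff(bumped["logn"]), 0.03, 0.12).sum()
            - stats.norm.logpdf(np.diff(base["logn"]), 0.03, 0.12).sum()
        )
        assert delta == pytest.approx(expected, abs=1e-10)

    def test_degenerate_process_sd_tends_to_minus_infinity(self):
        series = toy_series()
        spec = ModelSpec(CONSTANT_DETECTION, INFORMATIVE)
        state = {"logn": np.array([6.9, 7.0, 7.2]), "rbar": 0.0, "sigma_r": 1e-8}
        assert log_joint_density(spec, series, state) < -1e10

    def test_nonpositive_scales_raise(self):
        series = toy_series()
        spec = ModelSpec(CONSTANT_DETECTION, INFORMATIVE)
        state = {"logn": np.zeros(3) + 7.0, "rbar": 0.0, "sigma_r": 0.0}
        with pytest.raises(ValueError):
            log_joint_density(spec, series, state)

    def test_dimension_mismatch_raises(self):
        series = toy_series()
        spec = ModelSpec(CONSTANT_DETECTION, INFORMATIVE)
        with pytest.raises(ValueError):
            log_joint_density(spec, series, {"logn": np.zeros(5), "rbar": 0.0,
                                             "sigma_r": 0.1})


class TestSampler:
    def test_seeded_runs_are_bitwise_identical(self):
        spec, series = default_model_spec("ACP1")
        a = sample_posterior(spec, series, SMOKE)
        b = sample_posterior(spec, series, SMOKE)
        assert np.array_equal(a.logn, b.logn)
        assert np.array_equal(a.rbar, b.rbar)
        assert np.array_equal(a.sigma_r, b.sigma_r)

    def test_different_seeds_differ(self):
        spec, series = default_model_spec("ACP1")
        import dataclasses
        a = sample_posterior(spec, series, SMOKE)
        b = sample_posterior(spec, series, dataclasses.replace(SMOKE, seed=8))
        assert not np.array_equal(a.rbar, b.rbar)

    def test_draw_shapes_and_positivity(self):
        spec, series = default_model_spec("YKD4")
        d = sample_posterior(spec, series, SMOKE)
        S = SMOKE.n_retained
        assert d.logn.shape == (2, S, 13)
        assert np.all(d.sigma_r > 0) and np.all(d.sigma_d > 0)
        assert np.all(d.beta > 1.0)
        assert np.all(np.exp(d.logn) > 0)

    def test_prior_recovery_with_uninformative_data(self):
        """With observation SEs inflated x1e6 the data carry no information,
        so the marginal posteriors must reproduce the priors."""
        spec, series = default_model_spec("YKD1")
        blown = SurveySeries(series.population, tuple(
            SurveyObservation(o.year, o.estimate, o.se * 1e6) if o.observed else o
            for o in series.observations))
        settings = MCMCSettings(n_chains=3, n_iterations=20_000, n_burnin=5_000,
                                thin=5, n_adapt=2_000, seed=3)
        d = sample_posterior(spec, blown, settings)
        rbar = d.pooled("rbar")
        assert abs(rbar.mean()) < 0.01                      # prior mean 0
        assert rbar.std() == pytest.approx(0.1, rel=0.1)    # prior SD 0.1
        sig = d.pooled("sigma_r")
        assert sig.mean() == pytest.approx(3.0 / 20.0, rel=0.1)
        assert sig.std() == pytest.approx(math.sqrt(3.0) / 20.0, rel=0.15)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_burnin=5000, n_iterations=5000)
        with pytest.raises(ValueError):
            MCMCSettings(n_chains=0)


class TestGelmanRubin:
    def test_identical_chains_give_shrink_below_one(self):
        # B = 0, W = 1, n = 3 -> sqrt((n-1)/n) = sqrt(2/3)
        chains = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert gelman_rubin(chains) == pytest.approx(math.sqrt(2.0 / 3.0), abs=1e-12)

    def test_iid_chains_approach_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 20_000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_diverge(self):
        rng = np.random.default_rng(0)
        chains = np.array([np.zeros(50), np.full(50, 10.0)]) + 1e-3 * rng.standard_normal((2, 50))
        assert gelman_rubin(chains) > 10.0

    def test_errors(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 10)))
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((2, 10)))  # zero within-chain variance
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((2, 1)))


def _draws_from_pooled(values, years=(2019,)):
    arr = np.asarray(values, dtype=float)
    half = arr.size // 2
    rbar = np.stack([arr[0::2], arr[1::2]])  # interleave to keep chains alike
    return PosteriorDraws(years=tuple(years),
                          logn=np.zeros((2, half, len(years))),
                          rbar=rbar, sigma_r=np.full((2, half), 0.1))


class TestSummarize:
    def test_constant_draws(self):
        d = _draws_from_pooled(np.full(100, 3.25))
        s = summarize(d, "rbar")
        assert (s.mean, s.sd) == (3.25, 0.0)
        assert (s.cri_low, s.cri_high) == (3.25, 3.25)

    def test_grid_percentiles_follow_linear_interpolation(self):
        d = _draws_from_pooled(np.arange(1.0, 10_001.0))
        s = summarize(d, "rbar")
        # percentile p of the grid 1..n: 1 + (n-1) * p/100
        assert s.cri_low == pytest.approx(1 + 9999 * 0.025, abs=1e-9)
        assert s.cri_high == pytest.approx(1 + 9999 * 0.975, abs=1e-9)
        assert s.cri_low <= s.mean <= s.cri_high

    def test_unknown_parameter(self):
        d = _draws_from_pooled(np.arange(10.0))
        with pytest.raises(KeyError):
            summarize(d, "N_1999")
        with pytest.raises(KeyError):
            summarize(d, "sigma_d")


class TestPriorDerivations:
    def test_vcf_deviation_median_matches_quadrature_oracle(self):
        """Monte-Carlo quantiles of |log d| under sigma_d ~ Gamma(1, 10)
        agree with direct numerical integration of
        P(|log d| < c) = E_sigma[2 Phi(c/sigma) - 1]."""
        q50, q99 = prior_vcf_deviation_quantiles(1.0, 10.0, [0.5, 0.99],
                                                 n_draws=400_000, seed=5)

        def prob_below(c):
            f = lambda s: (2 * stats.norm.cdf(c / s) - 1) * stats.expon(scale=0.1).pdf(s)
            return integrate.quad(f, 0, np.inf, limit=200)[0]

        assert prob_below(q50) == pytest.approx(0.5, abs=0.01)
        assert prob_below(q99) == pytest.approx(0.99, abs=0.005)

    def test_half_normal_median_at_point_mass_sigma(self):
        # Gamma with huge shape ~ point mass at 0.1; median |N(0, 0.1)| = 0.6745 * 0.1
        (q,) = prior_vcf_deviation_quantiles(1e6, 1e7, [0.5], n_draws=200_000, seed=5)
        assert q == pytest.approx(0.06745, abs=0.002)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            prior_vcf_deviation_quantiles(-1.0, 10.0, [0.5])
        with pytest.raises(ValueError):
            prior_vcf_deviation_quantiles(1.0, 10.0, [1.5])

    def test_nest_to_aerial_ratio_propagation(self):
        prior = derive_observer_prior(15_584, 2_472, 5_714, 494)
        assert prior.ratio_mean == pytest.approx(2.73, abs=0.005)
        assert prior.ratio_sd == pytest.approx(0.49, abs=0.005)

    def test_moment_match_recovers_published_shape_rate(self):
        shape, rate = gamma_moment_match(1.72, 0.4374)
        assert shape == pytest.approx(15.5, abs=0.05)
        assert rate == pytest.approx(9.0, abs=0.05)

    def test_equal_estimates_zero_ses(self):
        prior = derive_observer_prior(5_714, 0.0, 5_714, 0.0)
        assert prior.ratio_mean == 1.0
        assert prior.ratio_sd == 0.0

    def test_gamma_round_trip(self):
        shape, rate = gamma_moment_match(0.15, 0.0866)
        assert shape / rate == pytest.approx(0.15)
        assert math.sqrt(shape) / rate == pytest.approx(0.0866)
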