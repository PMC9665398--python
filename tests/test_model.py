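"""Likelihood, priors, diagnostics, and sampler behaviour of the choice model."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr
from scipy.stats import gamma, norm

import avchoice as av
from avchoice.design import CarOffer, ChoiceRecord, ChoiceScenario, Country, Program
from avchoice.diagnostics import hdi, rhat
from avchoice.io import choices_to_frame
from avchoice.model import (
    HyperParams,
    ModelConfig,
    PosteriorSamples,
    PriorConfig,
    log_likelihood,
    log_prior,
    posterior_predictive_check,
    sample_posterior,
    utility_difference,
    wtp_report,
)

MOST15 = CarOffer(Program.MOST, 15)
MOST19 = CarOffer(Program.MOST, 19)
PED15 = CarOffer(Program.PEDESTRIANS, 15)
OCC15 = CarOffer(Program.OCCUPANTS, 15)

offers = st.builds(
    CarOffer,
    st.sampled_from(list(Program)),
    st.sampled_from([15.0, 19.0, 23.0]),
)


class TestUtilityDifference:
    def test_price_only_difference(self):
        assert utility_difference(MOST15, MOST19, ped=-99.0, occ=42.0) == 4.0

    def test_identical_cars_have_zero_difference(self):
        assert utility_difference(MOST15, MOST15, ped=1.0, occ=2.0) == 0.0

    def test_program_utility_substitution(self):
        assert utility_difference(OCC15, MOST15, ped=0.0, occ=-3.17) == pytest.approx(-3.17)

    @settings(deadline=None, max_examples=100)
    @given(offers, offers, st.floats(-20, 20), st.floats(-20, 20))
    def test_antisymmetric_under_swap(self, a, b, ped, occ):
        assert utility_difference(a, b, ped, occ) == pytest.approx(
            -utility_difference(b, a, ped, occ)
        )


class TestChoiceProbability:
    def test_zero_difference_is_even_odds(self):
        assert av.choice_probability(0.0, 0.7) == pytest.approx(0.5)

    def test_large_difference_saturates(self):
        assert av.choice_probability(1e6, 0.3) == pytest.approx(1.0)
        assert av.choice_probability(-1e6, 0.3) == pytest.approx(0.0)

    def test_standard_normal_cdf_value(self):
        # Phi(4 * 0.291) = Phi(1.164)
        assert av.choice_probability(4.0, 0.291) == pytest.approx(0.8778, abs=1e-4)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(-30, 30), st.floats(0.01, 3.0))
    def test_choice_probabilities_sum_to_one(self, du, tau):
        p_a = av.choice_probability(du, tau)
        p_b = av.choice_probability(-du, tau)
        assert p_a + p_b == pytest.approx(1.0)
        assert av.choice_probability(du + 1e-3, tau) >= p_a  # increasing in dU


class TestLogLikelihood:
    scenarios = [
        ChoiceScenario(1, PED15, MOST19),  # dU = 4 + ped
        ChoiceScenario(2, MOST15, MOST15.__class__(Program.OCCUPANTS, 15)),  # dU = -occ
    ]

    def _individuals(self, ped=0.0, occ=0.0, tau=0.291):
        return pd.DataFrame({"ped": [ped], "occ": [occ], "tau": [tau]}, index=["P1"])

    def test_single_fair_trial(self):
        rec = [ChoiceRecord("P1", Country.UK, 2, "A")]
        ind = self._individuals(occ=0.0)
        assert log_likelihood(rec, self.scenarios, ind) == pytest.approx(math.log(0.5))

    def test_empty_records_give_zero(self):
        assert log_likelihood([], self.scenarios, self._individuals()) == 0.0

    def test_hand_summed_bernoulli_terms(self):
        # p = (Phi(1.164), 0.5, Phi(1.164)) with choices (A, A, B)
        scen = [
            ChoiceScenario(1, PED15, MOST19),
            ChoiceScenario(2, MOST15, OCC15),
            ChoiceScenario(3, PED15, MOST19),
        ]
        rec = [
            ChoiceRecord("P1", Country.UK, 1, "A"),
            ChoiceRecord("P1", Country.UK, 2, "A"),
            ChoiceRecord("P1", Country.UK, 3, "B"),
        ]
        ind = self._individuals(ped=0.0, occ=0.0, tau=0.291)
        p = float(ndtr(1.164))
        expected = math.log(p) + math.log(0.5) + math.log(1 - p)
        assert log_likelihood(rec, scen, ind) == pytest.approx(expected, rel=1e-6)

    def test_impossible_choice_returns_neg_inf(self):
        rec = [ChoiceRecord("P1", Country.UK, 1, "B")]
        ind = self._individuals(ped=math.inf, tau=1.0)
        assert log_likelihood(rec, self.scenarios, ind) == -math.inf


class TestLogPrior:
    def test_non_positive_precision_is_neg_inf(self):
        assert log_prior(HyperParams(0, 0, 1, 0, 1)) == -math.inf
        assert log_prior(HyperParams(0, 0, -1, 1, 1)) == -math.inf

    def test_closed_form_at_arbitrary_hypers(self):
        h = HyperParams(HPed=-2.0, HOcc=1.0, Htau=0.3, Ht=0.5, Ht2=2.0)
        expected = (
            norm.logpdf(-2.0, 0, math.sqrt(10))
            + norm.logpdf(1.0, 0, math.sqrt(10))
            + sum(gamma.logpdf(x, 0.5, scale=2.0) for x in (0.3, 0.5, 2.0))
        )
        assert log_prior(h) == pytest.approx(expected, rel=1e-10)

    def test_individual_at_population_means_adds_density_maxima(self):
        h = HyperParams(HPed=-10.7, HOcc=-3.17, Htau=0.291, Ht=0.25, Ht2=100.0)
        ind = pd.DataFrame({"ped": [-10.7], "occ": [-3.17], "tau": [0.291]}, index=["P1"])
        delta = log_prior(h, ind) - log_prior(h)
        expected = (
            2 * norm.logpdf(0.0, 0, 1 / math.sqrt(0.25))
            + norm.logpdf(0.0, 0, 1 / math.sqrt(100.0))
        )
        assert delta == pytest.approx(expected, rel=1e-10)


class TestRhat:
    def test_converged_chains_near_one(self, rng):
        draws = rng.normal(size=(3, 10_000))
        assert rhat(draws) < 1.01

    def test_dispersed_chains_flagged(self, rng):
        draws = np.stack([rng.normal(0, 1, 500), rng.normal(100, 1, 500)])
        assert rhat(draws) > 1.5

    def test_constant_equal_chains_convention(self):
        assert rhat(np.ones((3, 100))) == 1.0

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


class TestHdi:
    def test_symmetric_samples_contain_zero(self, rng):
        lo, hi = hdi(rng.normal(size=5_000), 0.95)
        assert lo < 0 < hi

    def test_uniform_interval_length(self, rng):
        lo, hi = hdi(rng.uniform(0, 1, 10_000), 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_exhaustive_window_example(self):
        assert hdi(np.array([1.0, 2.0, 3.0, 100.0]), 0.75) == (1.0, 3.0)

    def test_matches_brute_force_window_search(self, rng):
        samples = np.sort(rng.gamma(2.0, 1.0, 200))
        mass = 0.9
        k = int(np.ceil(mass * samples.size))
        best = min(
            ((samples[i + k - 1] - samples[i], (samples[i], samples[i + k - 1]))
             for i in range(samples.size - k + 1)),
            key=lambda t: t[0],
        )[1]
        assert hdi(samples, mass) == best

    def test_matches_arviz_on_unimodal_samples(self, rng):
        az = pytest.importorskip("arviz")
        samples = rng.normal(size=4_000)
        lo, hi = hdi(samples, 0.9)
        ref = az.hdi(samples, hdi_prob=0.9)
        # arviz's window is one sample wider; agreement to sample spacing
        assert lo == pytest.approx(ref[0], abs=0.05)
        assert hi == pytest.approx(ref[1], abs=0.05)


class TestModelConfig:
    def test_rejects_single_chain(self):
        with pytest.raises(ValueError):
            ModelConfig(n_chains=1)

    def test_rejects_burnin_not_below_samples(self):
        with pytest.raises(ValueError):
            ModelConfig(n_samples=100, n_burnin=100)


class TestSampler:
    def test_same_seed_is_bitwise_identical(self):
        spec = av.load_preset("uk-paper", n_participants=5)
        tables = av.simulate_survey(spec, seed=0)
        cfg = ModelConfig(n_chains=2, n_samples=400, n_burnin=100, seed=3)
        a = sample_posterior(tables["choices"], tables["scenarios"], cfg)
        b = sample_posterior(tables["choices"], tables["scenarios"], cfg)
        assert np.array_equal(a.hyper, b.hyper)
        assert np.array_equal(a.individual, b.individual)

    def test_rhat_reported_for_every_parameter(self, small_fit):
        p = small_fit.posterior_
        assert set(p.rhat_hyper) == {"HPed", "HOcc", "Htau", "Ht", "Ht2"}
        assert p.rhat_individual.shape == (12, 3)
        assert np.isfinite(p.rhat_individual.to_numpy()).all()

    def test_pricier_pedestrian_offers_lower_fitted_hped(self):
        """Monotonicity: choices generated with PEDESTRIANS offers made £2k
        dearer, but fitted against the stated prices, push the extra
        avoidance into a lower pedestrian utility."""
        spec = av.load_preset("uk-paper", n_participants=24)
        tables = av.simulate_survey(spec, seed=6)
        cfg = ModelConfig(n_chains=2, n_samples=1500, n_burnin=400, seed=8)
        base = sample_posterior(tables["choices"], tables["scenarios"], cfg)
        bumped = [
            ChoiceScenario(
                s.scenario_id,
                CarOffer(s.car_a.program, s.car_a.price
                         + (2.0 if s.car_a.program is Program.PEDESTRIANS else 0.0)),
                CarOffer(s.car_b.program, s.car_b.price
                         + (2.0 if s.car_b.program is Program.PEDESTRIANS else 0.0)),
            )
            for s in tables["scenarios"]
        ]
        records = av.simulate_choices(tables["individuals"], bumped, seed=6)
        alt = sample_posterior(records, tables["scenarios"], cfg)
        assert alt.mean("HPed") < base.mean("HPed") - 0.5


class TestEstimatorApi:
    def test_get_set_params_round_trip(self):
        m = av.HierarchicalProbitChoiceModel(n_samples=123, n_burnin=10)
        params = m.get_params()
        m2 = av.HierarchicalProbitChoiceModel().set_params(**params)
        assert m2.get_params() == params

    def test_unknown_param_rejected(self):
        with pytest.raises(ValueError):
            av.HierarchicalProbitChoiceModel().set_params(bogus=1)

    def test_unfitted_model_raises(self):
        with pytest.raises(RuntimeError):
            av.HierarchicalProbitChoiceModel().predict_proba(pd.DataFrame())

    def test_predict_proba_and_score(self, small_survey, small_fit):
        _, tables = small_survey
        frame = choices_to_frame(tables["scenarios"], tables["choices"])
        proba = small_fit.predict_proba(frame)
        assert ((proba >= 0) & (proba <= 1)).all()
        assert small_fit.score(frame) > 0.5  # far better than coin flipping


def _constant_posterior(hyper_values, individual_values, participant_ids):
    """Degenerate posterior with all draws equal (rhat = 1 by convention)."""
    n_draw = 4
    hyper = np.tile(np.asarray(hyper_values, float), (2, n_draw, 1))
    ind = np.tile(np.asarray(individual_values, float), (2, n_draw, 1, 1))
    return PosteriorSamples(
        hyper=hyper, individual=ind, participant_ids=participant_ids,
        hdi_mass=0.95, accept_rate_htau=1.0,
    )


class TestWtpReport:
    def test_uk_style_premiums_and_reference(self):
        post = _constant_posterior(
            [-10.7, -3.17, 0.291, 0.25, 100.0], [[[-10.7, -3.17, 0.291]]], ["P1"]
        )
        report = wtp_report(post)
        assert report.premiums["MOST"][0] == 0.0
        assert report.premiums["PEDESTRIANS"][0] == pytest.approx(10_700)
        assert report.premiums["OCCUPANTS"][0] == pytest.approx(3_170)
        assert not report.tau_mass_flag  # 0.291 * 10 = 2.9 sd above zero

    def test_favoured_program_reports_price_decrease(self):
        post = _constant_posterior(
            [4.18, -6.47, 0.388, 0.25, 100.0], [[[4.18, -6.47, 0.388]]], ["P1"]
        )
        report = wtp_report(post)
        assert report.premiums["PEDESTRIANS"][0] == pytest.approx(-4_180)
        assert report.premiums["OCCUPANTS"][0] == pytest.approx(6_470)

    def test_flags_tau_hierarchy_mass_below_zero(self):
        post = _constant_posterior(
            [0.0, 0.0, 0.1, 0.25, 25.0], [[[0.0, 0.0, 0.1]]], ["P1"]
        )
        # P(tau_new < 0) = Phi(-0.1 * 5) = 0.31 >> 1%
        assert wtp_report(post).tau_mass_flag


class TestPosteriorPredictiveCheck:
    def _deterministic_setup(self, design):
        ind = pd.DataFrame(
            {"ped": [-10.7] * 10, "occ": [-3.17] * 10, "tau": [1000.0] * 10},
            index=[f"P{i}" for i in range(10)],
        )
        records = av.simulate_choices(ind, design, seed=0)
        post = _constant_posterior(
            [-10.7, -3.17, 1000.0, 0.25, 100.0],
            [[[-10.7, -3.17, 1000.0]] * 10],
            list(ind.index),
        )
        return post, records

    def test_perfect_separation_gives_hit_rate_one(self, design):
        post, records = self._deterministic_setup(design)
        ppc = posterior_predictive_check(post, records, design)
        assert ppc.attrs["hit_rate"] == 1.0
        assert np.allclose(ppc["observed_share"], ppc["predicted_share"])

    def test_shuffled_labels_drop_hit_rate_to_chance(self, design, rng):
        post, records = self._deterministic_setup(design)
        flips = rng.random(len(records)) < 0.5
        shuffled = [
            ChoiceRecord(r.participant_id, r.country, r.scenario_id,
                         ("B" if r.choice == "A" else "A") if f else r.choice)
            for r, f in zip(records, flips)
        ]
        ppc = posterior_predictive_check(post, shuffled, design)
        se = np.sqrt(0.25 / len(records))
        assert abs(ppc.attrs["hit_rate"] - 0.5) < 4 * se
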