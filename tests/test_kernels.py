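"""Psychophysical-kernel model: likelihood, prior, posterior, transfer."""

import numpy as np
import pytest
from scipy.special import expit

import oridisc as od
from oridisc.kernels import (KernelModel, KernelPrior, _eval_mean_ll,
                             circular_second_difference, consistency_score,
                             kernel_log_prior, kernel_loglik, pack_params,
                             select_hyperparams, transfer_loglik)
from oridisc.observer import choice_probability_positive


class TestLoglik:
    def test_chance_model(self):
        u = np.random.default_rng(0).standard_normal((40, 12))
        c = np.random.default_rng(1).choice([-1, 1], 40)
        ll = kernel_loglik((np.zeros(12), 0.0, 0.0, 0.0), u, c)
        assert ll == pytest.approx(40 * np.log(0.5))

    def test_lapse_asymptote(self):
        # z -> +inf with lapses (0.1, 0.2): q = 0.8 for a positive choice
        u = np.zeros((1, 12))
        ll = kernel_loglik((np.zeros(12), 50.0, 0.1, 0.2), u, np.array([1]))
        assert ll == pytest.approx(np.log(0.8), abs=1e-9)

    def test_single_weight_direct_evaluation(self):
        w = np.zeros(12)
        w[0] = 1.0
        u = np.zeros((1, 12))
        u[0, 0] = 1.0
        ll = kernel_loglik((w, 0.0, 0.0, 0.0), u, np.array([1]))
        assert ll == pytest.approx(np.log(expit(1.0)), abs=1e-12)
        assert ll == pytest.approx(np.log(0.7311), abs=1e-4)

    def test_choice_negation_symmetry_with_equal_lapses(self):
        rng = np.random.default_rng(2)
        u = rng.standard_normal((60, 12))
        c = rng.choice([-1, 1], 60)
        w = rng.standard_normal(12)
        a = kernel_loglik((w, 0.4, 0.07, 0.07), u, c)
        b = kernel_loglik((-w, -0.4, 0.07, 0.07), u, -c)
        assert a == pytest.approx(b, rel=1e-12)


class TestPrior:
    def test_smoothness_term_annihilates_constants(self):
        d = circular_second_difference(12)
        np.testing.assert_allclose(d @ np.ones(12), 0.0, atol=1e-12)
        # hence the log prior of a constant kernel is pure ridge + bias
        prior = KernelPrior()
        c = 0.7
        lp = kernel_log_prior((np.full(12, c), 0.0, 0.0, 0.0), prior)
        assert lp == pytest.approx(-0.5 * prior.ridge * 12 * c**2, rel=1e-12)

    @pytest.mark.parametrize("ridge,smooth", [(0.1, 0.01), (6, 0.5), (50, 20)])
    def test_precision_positive_definite(self, ridge, smooth):
        p = KernelPrior(ridge=ridge, smooth=smooth).weight_precision()
        assert np.linalg.eigvalsh(p).min() > 0


class TestPosterior:
    def test_same_seed_identical_sample_stream(self, session_800):
        trials, energy = session_800
        obs = od.kernel_battery()[0]
        sim = od.simulate_observer_choices(trials, energy, obs, seed=3)
        model = KernelModel.from_session(sim, energy)
        a = model.fit(n_samples=200, n_warmup=200, seed=9)
        b = model.fit(n_samples=200, n_warmup=200, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_posterior_contracts_with_sample_size(self, interleaved_session,
                                                  subset):
        trials, energy = interleaved_session
        obs = od.kernel_battery()[0]
        sim = od.simulate_observer_choices(trials, energy, obs, seed=4)
        small = subset(sim, energy, 200)
        large = subset(sim, energy, 800)
        sd_small = KernelModel.from_session(*small).fit(
            n_samples=400, n_warmup=400, seed=5).w_theta.std(axis=0).mean()
        sd_large = KernelModel.from_session(*large).fit(
            n_samples=400, n_warmup=400, seed=5).w_theta.std(axis=0).mean()
        assert sd_large < sd_small

    def test_pure_chance_observer_shrinks_to_prior(self, session_800):
        trials, energy = session_800
        obs = od.GroundTruthObserver(w_theta=np.zeros(12))
        sim = od.simulate_observer_choices(trials, energy, obs, seed=6)
        res = KernelModel.from_session(sim, energy).fit(
            n_samples=500, n_warmup=400, seed=7)
        prior_sd = np.sqrt(np.diag(KernelPrior().implied_weight_covariance()))
        assert np.all(np.abs(res.posterior_mean[:12]) < 2 * prior_sd)

    def test_too_few_trials_is_error(self, session_800):
        trials, energy = session_800
        with pytest.raises(ValueError, match="usable trials"):
            KernelModel.from_session(trials.iloc[:50], energy, min_trials=100)


class TestTransfer:
    def test_negated_weights_equal_sign_flipped_regressors(self):
        rng = np.random.default_rng(8)
        u = rng.standard_normal((30, 12))
        c = rng.choice([-1, 1], 30)
        theta = pack_params(rng.standard_normal(12), 0.0, 0.04, 0.04)
        neg = theta.copy()
        neg[:12] = -theta[:12]
        assert _eval_mean_ll(neg, u, c) == pytest.approx(
            _eval_mean_ll(theta, -u, c), rel=1e-12)

    def test_shared_strategy_null(self, interleaved_session):
        trials, energy = interleaved_session
        mixed = od.kernel_battery()[6]
        sim = od.simulate_observer_choices(trials, energy, mixed, seed=70)
        res = transfer_loglik(sim, energy, seed=170)
        assert abs(res.diff) <= 2 * res.diff_se

    def test_orthogonal_strategies_detected(self, interleaved_session,
                                            subset):
        trials, energy = interleaved_session
        trials, energy = subset(trials, energy, 1000)
        card, obl = od.kernel_battery()[0], od.kernel_battery()[1]
        rng = np.random.default_rng(54)
        choice = np.empty(len(trials), dtype=int)
        for task, obs in (("cardinal", card), ("oblique", obl)):
            m = (trials["task"] == task).to_numpy()
            q = choice_probability_positive(energy.u[m], obs)
            choice[m] = np.where(rng.random(m.sum()) < q, 1, -1)
        sim = trials.copy()
        sim["choice"] = choice
        res = transfer_loglik(sim, energy, seed=55)
        assert res.diff > 0
        assert res.diff / res.diff_se > 3.0

    def test_single_task_session_is_error(self, session_800):
        trials, energy = session_800
        single = trials.copy()
        single["task"] = "cardinal"
        single["choice"] = 1
        with pytest.raises(ValueError, match="both tasks"):
            transfer_loglik(single, energy)


class TestConsistency:
    @pytest.fixture(scope="class")
    def two_fits(self, session_800):
        trials, energy = session_800
        card, obl = od.kernel_battery()[0], od.kernel_battery()[1]
        sim_c = od.simulate_observer_choices(trials, energy, card, seed=20)
        sim_o = od.simulate_observer_choices(trials, energy, obl, seed=21)
        m_c = KernelModel.from_session(sim_c, energy)
        fit_c = m_c.fit(n_samples=400, n_warmup=400, seed=22)
        fit_o = KernelModel.from_session(sim_o, energy).fit(
            n_samples=400, n_warmup=400, seed=23)
        return m_c, fit_c, fit_o

    def test_self_prediction_is_exactly_zero(self, two_fits):
        m_c, fit_c, _ = two_fits
        assert consistency_score(fit_c, m_c.u, m_c.choices, fit_c) == 0.0

    def test_orthogonal_source_scores_negative(self, two_fits):
        m_c, fit_c, fit_o = two_fits
        assert consistency_score(fit_o, m_c.u, m_c.choices, fit_c) < 0

    def test_invariant_to_trial_order(self, two_fits):
        m_c, fit_c, fit_o = two_fits
        perm = np.random.default_rng(24).permutation(len(m_c.choices))
        a = consistency_score(fit_o, m_c.u, m_c.choices, fit_c)
        b = consistency_score(fit_o, m_c.u[perm], m_c.choices[perm], fit_c)
        assert a == pytest.approx(b, rel=1e-10)


class TestHyperparams:
    def test_singleton_grid_returned_directly(self, session_800):
        trials, energy = session_800
        only = KernelPrior()
        assert select_hyperparams(trials, energy, [only]) is only

    def test_smoother_truth_selects_stronger_smoothing(self, session_800):
        trials, energy = session_800
        grid = [KernelPrior(smooth=0.05), KernelPrior(smooth=5.0)]
        th = np.radians(2.0 * np.arange(0, 180, 15))
        smooth_w = 0.8 * np.cos(th)
        jagged_w = 0.8 * np.array([1, -1] * 6, dtype=float)
        picks = {}
        for name, w in (("smooth", smooth_w), ("jagged", jagged_w)):
            obs = od.GroundTruthObserver(w_theta=w, lapse_pos=0.03,
                                         lapse_neg=0.03)
            sim = od.simulate_observer_choices(trials, energy, obs, seed=103)
            picks[name] = select_hyperparams(sim, energy, grid,
                                             seed=104).smooth
        assert picks["smooth"] >= picks["jagged"]

    def test_selection_deterministic(self, session_800):
        trials, energy = session_800
        obs = od.kernel_battery()[0]
        sim = od.simulate_observer_choices(trials, energy, obs, seed=30)
        grid = [KernelPrior(ridge=3.0), KernelPrior(ridge=12.0)]
        a = select_hyperparams(sim, energy, grid, seed=31)
        b = select_hyperparams(sim, energy, grid, seed=31)
        assert a is b
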