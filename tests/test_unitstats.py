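"""Tuning curves, f' and d', choice probability, and the choice decoder."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import oridisc as od
from oridisc.cleanup import anscombe
from oridisc.unitstats import (_exceedance, compute_cp, compute_dprime,
                               decode_choice, estimate_fprime,
                               fit_orientation_tuning)

ORIS = np.tile(np.arange(0.0, 180.0, 15.0), 6)   # 72 grating trials


class TestTuning:
    def test_delta_tuning(self):
        resp = (ORIS == 45.0).astype(float) * 10
        fit = fit_orientation_tuning(ORIS, resp, n_boot=50, seed=0)
        assert fit.circular_variance < 0.01
        assert fit.preferred_deg == pytest.approx(45.0, abs=0.5)

    def test_flat_tuning(self):
        fit = fit_orientation_tuning(ORIS, np.ones_like(ORIS), n_boot=50,
                                     seed=0)
        assert fit.circular_variance > 0.99

    def test_preferred_orientation_recovered_within_5_degrees(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rate = 10 + 20 * np.exp(
                2.0 * (np.cos(np.radians(2 * (ORIS - 30.0))) - 1.0))
            resp = anscombe(rng.poisson(rate))
            fit = fit_orientation_tuning(ORIS, resp, n_boot=50, seed=seed)
            d = abs((fit.preferred_deg - 30.0 + 90) % 180 - 90)
            hits += d <= 5.0
        assert hits >= 19   # >= 95% of seeds

    def test_all_zero_responses_error(self):
        with pytest.raises(ValueError):
            fit_orientation_tuning(ORIS, np.zeros_like(ORIS))


class TestFprime:
    def test_linear_tuning_identity_limit(self):
        s = np.linspace(-97, 97, 400)
        r = 0.02 * s
        fp, _ = estimate_fprime(r, s, lambda_f=1e6, n_boot=10, seed=0)
        assert fp == pytest.approx(0.02, rel=1e-6)

    def test_saturating_tuning_recovers_zero_signal_slope(self):
        rng = np.random.default_rng(1)
        tr = od.gen_trial_schedule(800, seed=1)
        s = tr["signal_s"].to_numpy()
        r = 0.02 * 30 * np.tanh(s / 30.0) + rng.normal(0, 0.2, len(s))
        fp, boot = estimate_fprime(r, s, lambda_f=30.0, n_boot=100, seed=2)
        assert fp == pytest.approx(0.02, rel=0.10)
        assert len(boot) == 100

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(3)
        tr = od.gen_trial_schedule(400, seed=3)
        s = tr["signal_s"].to_numpy()
        r = 0.01 * s + rng.normal(0, 0.3, len(s))
        fp_pos, _ = estimate_fprime(r, s, n_boot=10, seed=4)
        fp_neg, _ = estimate_fprime(r, -s, n_boot=10, seed=4)
        assert fp_pos == pytest.approx(-fp_neg, rel=1e-9)

    def test_low_signal_trials_never_used(self):
        s = np.full(100, 3.0)   # all below the 5.67% floor
        with pytest.raises(ValueError):
            estimate_fprime(np.zeros(100), s)


class TestDprime:
    def test_printed_formula(self):
        assert compute_dprime(0.02, 1.0) == pytest.approx(1.0)
        assert compute_dprime(0.0, 2.0) == 0.0
        assert compute_dprime(0.02, 2.0) == pytest.approx(
            compute_dprime(0.02, 1.0) / 2)

    def test_zero_sigma_error(self):
        with pytest.raises(ValueError):
            compute_dprime(0.1, 0.0)


def _cp_trials(n, seed, shift=0.0):
    rng = np.random.default_rng(seed)
    tr = od.gen_trial_schedule(n, seed=seed, level_set=[0.0])
    c = rng.choice([-1, 1], n)
    tr["choice"] = c
    r = rng.normal(0, 1, n) + 0.5 * shift * c    # class separation = shift SD
    return r, tr


class TestChoiceProbability:
    def test_null_cp_near_half(self):
        r, tr = _cp_trials(2000, 5)
        res = compute_cp(r, tr, n_boot=200, seed=6)
        assert abs(res.cp - 0.5) < 0.02
        assert not res.significant

    def test_perfect_separation(self):
        rng = np.random.default_rng(7)
        tr = od.gen_trial_schedule(200, seed=7, level_set=[0.0])
        c = rng.choice([-1, 1], 200)
        tr["choice"] = c
        r = c * 1.0 + 0.01 * rng.random(200)
        res = compute_cp(r, tr, n_boot=50, seed=8)
        assert res.cp == 1.0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=1, max_size=8),
           st.lists(st.integers(0, 3), min_size=1, max_size=8))
    def test_exceedance_equals_brute_force_on_small_cases(self, pos, neg):
        pos = np.asarray(pos, float)
        neg = np.asarray(neg, float)
        brute = np.mean([1.0 if a > b else (0.5 if a == b else 0.0)
                         for a in pos for b in neg])
        assert _exceedance(pos, neg) == pytest.approx(brute, abs=1e-12)

    def test_sign_convention_coupling(self):
        """Negating the stimulus/choice sign convention flips f' and maps
        CP -> 1 - CP; the product (CP - 0.5) * sign(d') is invariant."""
        rng = np.random.default_rng(10)
        n = 1500
        tr = od.gen_trial_schedule(n, seed=10)
        s = tr["signal_s"].to_numpy()
        c = np.where(rng.random(n) < 0.5, 1, -1)
        tr["choice"] = c
        r = 0.01 * s + 0.2 * c + rng.normal(0, 1, n)
        fp, _ = estimate_fprime(r, s, n_boot=10, seed=11)
        cp = compute_cp(r, tr, n_boot=50, seed=12).cp
        flipped = tr.copy()
        flipped["signal_s"] = -s
        flipped["choice"] = -c
        fp2, _ = estimate_fprime(r, -s, n_boot=10, seed=11)
        cp2 = compute_cp(r, flipped, n_boot=50, seed=12).cp
        assert fp2 == pytest.approx(-fp, rel=1e-9)
        assert cp2 == pytest.approx(1.0 - cp, abs=0.02)
        assert np.sign((cp - 0.5) * np.sign(fp)) == np.sign(
            (cp2 - 0.5) * np.sign(fp2))

    def test_one_choice_class_empty_is_flagged(self):
        tr = od.gen_trial_schedule(100, seed=13, level_set=[0.0])
        tr["choice"] = 1
        with pytest.raises(ValueError, match="choice class empty"):
            compute_cp(np.zeros(100), tr, n_boot=10, seed=14)

    def test_sparse_levels_excluded_by_trial_count_rule(self):
        tr = od.gen_trial_schedule(100, seed=15, level_set=[0.0, 11.05],
                                   zero_fraction=0.9)
        tr["choice"] = np.random.default_rng(15).choice([-1, 1], 100)
        res = compute_cp(np.random.default_rng(16).normal(0, 1, 100), tr,
                         n_boot=20, seed=17, min_trials_per_level=20)
        assert res.n_trials < 100   # rare levels dropped


class TestDecoder:
    def test_shuffled_labels_are_chance(self):
        rng = np.random.default_rng(18)
        r = rng.normal(0, 1, (400, 15))
        labels = rng.choice([-1, 1], 400)
        res = decode_choice(r, labels, seed=19)
        band = 2 * np.sqrt(0.25 / 400)
        assert abs(res.accuracy - 0.5) < 3 * band + 0.02
        assert abs(res.shuffle_accuracy - 0.5) < 3 * band + 0.02

    def test_strong_choice_axis_decoded(self):
        rng = np.random.default_rng(20)
        labels = rng.choice([-1, 1], 400)
        r = rng.normal(0, 1, (400, 15))
        r[:, :5] += 1.2 * labels[:, None]
        res = decode_choice(r, labels, seed=21)
        assert res.accuracy > 0.9

    def test_population_decoder_beats_best_single_unit(self):
        """Pooling oracle: held-out LDA accuracy is at least the accuracy
        implied by the best single unit's CP (median over 10 seeds)."""
        margins = []
        for seed in range(10):
            rng = np.random.default_rng(seed + 30)
            n = 600
            labels = rng.choice([-1, 1], n)
            r = rng.normal(0, 1, (n, 10)) + 0.3 * labels[:, None]
            dec = decode_choice(r, labels, seed=seed)
            best = 0.5
            for i in range(10):
                # implied accuracy of a single-unit threshold rule
                auc = _exceedance(r[labels == 1, i], r[labels == -1, i])
                best = max(best, 0.5 + abs(auc - 0.5))
            margins.append(dec.accuracy - best)
        assert np.median(margins) >= 0.0
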