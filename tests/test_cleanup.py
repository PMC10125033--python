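"""Variance stabilization, the VBEM cleanup model, and outlier handling."""

import numpy as np
import pytest
from scipy import stats

import oridisc as od
from oridisc.cleanup import (CleanupModel, ExclusionCriteria, anscombe,
                             apply_exclusions, clean_responses,
                             detect_outliers, inverse_anscombe,
                             iterate_cleanup, surprisal_bits)


class TestAnscombe:
    def test_count_zero_value(self):
        assert anscombe(0) == pytest.approx(2 * np.sqrt(3 / 8))
        assert anscombe(0) == pytest.approx(1.2247, abs=1e-4)

    def test_unbiased_inverse_recovers_rate(self):
        rng = np.random.default_rng(1)
        for lam in (5.0, 20.0, 100.0):
            r = anscombe(rng.poisson(lam, 100_000))
            assert inverse_anscombe(r.mean()) == pytest.approx(lam, rel=0.01)

    def test_inverse_below_range_returns_zero_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert inverse_anscombe(0.3) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            anscombe(-1)


class TestSurprisal:
    def test_printed_values_at_rate_ten(self):
        # exact pmf/entropy oracle: typical observation is mildly un-surprising
        assert surprisal_bits(10, 10.0) == pytest.approx(-0.71, abs=0.02)
        # a 3x count is far beyond the 8-bit cell mask threshold
        assert surprisal_bits(30, 10.0) == pytest.approx(18.8, abs=0.1)

    def test_definitional_centering(self):
        rng = np.random.default_rng(2)
        for lam in (5.0, 50.0):
            s = surprisal_bits(rng.poisson(lam, 100_000), lam)
            assert abs(s.mean()) < 0.05

    def test_positive_rate_required(self):
        with pytest.raises(ValueError):
            surprisal_bits(3, 0.0)


def _session(n, n_units, seed, **pop_kw):
    rng = np.random.default_rng(seed)
    tr = od.gen_trial_schedule(n, seed=seed)
    tr["choice"] = rng.choice([-1, 1], n)
    pop = od.GroundTruthPopulation.default(n_units=n_units, seed=seed + 1,
                                           **pop_kw)
    return tr, pop


class TestCleanupModel:
    def test_null_data_shrinks_loadings(self):
        tr, pop = _session(300, 6, 3, drift_loading_wx=np.zeros(6))
        samp = od.simulate_population_responses(tr, pop, seed=4)
        fit = CleanupModel(samp.r, tr).fit()
        # wc is estimated from n ~ 300 trials of unit-variance noise, so its
        # sampling SE is ~ 1/sqrt(n); all units must sit within ~4 SE of zero
        se = 1.0 / np.sqrt(len(tr))
        assert np.all(np.abs(fit.choice_loading) < 4 * se)
        assert np.abs(fit.choice_loading).mean() < 2 * se
        assert np.all(fit.drift_component.std(axis=0) < 0.3)

    def test_choice_loading_sign_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tr = od.gen_trial_schedule(250, seed=seed)
            tr["choice"] = rng.choice([-1, 1], 250)
            pop = od.GroundTruthPopulation.default(
                n_units=3, seed=seed + 50, drift_loading_wx=np.zeros(3),
                choice_loading_wc=np.full(3, 0.4))
            samp = od.simulate_population_responses(tr, pop, seed=seed + 100)
            fit = CleanupModel(samp.r, tr).fit()
            hits += np.all(fit.choice_loading > 0)
        assert hits >= 18   # sign correct in >= 90% of seeds

    def test_clean_responses_is_identity_at_zero_loading(self):
        tr, pop = _session(150, 4, 5, drift_loading_wx=np.zeros(4))
        samp = od.simulate_population_responses(tr, pop, seed=6)
        fit = CleanupModel(samp.r, tr).fit()
        fit.drift_loading[:] = 0.0
        np.testing.assert_array_equal(clean_responses(samp.r, fit), samp.r)

    def test_masked_cells_stay_masked(self):
        tr, pop = _session(150, 4, 7)
        samp = od.simulate_population_responses(tr, pop, seed=8)
        r = samp.r.copy()
        r[10, 2] = np.nan
        fit = CleanupModel(r, tr).fit()
        assert np.isnan(clean_responses(r, fit)[10, 2])

    def test_drift_subtraction_halves_lag1_autocorrelation(self):
        tr, pop = _session(400, 10, 9, drift_loading_wx=np.full(10, 0.8))
        samp = od.simulate_population_responses(tr, pop, seed=10)
        fit = CleanupModel(samp.r, tr).fit()
        cleaned = clean_responses(samp.r, fit)

        def mean_abs_lag1(m):
            out = []
            for i in range(m.shape[1]):
                v = m[:, i] - m[:, i].mean()
                out.append((v[:-1] @ v[1:]) / (v @ v))
            return np.mean(np.abs(out))

        assert mean_abs_lag1(cleaned) < 0.5 * mean_abs_lag1(samp.r)

    def test_tuning_functions_tied_at_zero_signal(self):
        tr, pop = _session(300, 3, 11)
        samp = od.simulate_population_responses(tr, pop, seed=12)
        fit = CleanupModel(samp.r, tr).fit()
        s_a, f_a = fit.tuning_curve(0, "cardinal")
        s_b, f_b = fit.tuning_curve(0, "oblique")
        assert f_a[s_a == 0.0] == f_b[s_b == 0.0]


class TestOutliers:
    @pytest.fixture(scope="class")
    def clean_counts(self):
        rng = np.random.default_rng(13)
        tr = od.gen_trial_schedule(300, seed=13)
        tr["choice"] = rng.choice([-1, 1], 300)
        pop = od.GroundTruthPopulation.default(
            n_units=12, seed=14, drift_loading_wx=np.zeros(12))
        samp = od.simulate_population_responses(tr, pop, seed=15,
                                                emit_counts=True)
        return tr, samp.counts.astype(float)

    def test_null_removal_rate_matches_exact_poisson_oracle(self,
                                                            clean_counts):
        """Exact Poisson oracle for the trial rule's null rate: with per-cell
        P(surprisal > 2 bits) = p (computed exactly from the pmf), a trial of
        12 units is removed with probability P(Binom(12, p) >= 2)."""
        from scipy import stats as st
        tr, counts = clean_counts
        r = anscombe(counts)
        fit = CleanupModel(r, tr).fit()
        rep = detect_outliers(r, fit, counts=counts)
        # worst-case exact per-cell rate over the session's count range
        p_cell = 0.0
        for lam in np.linspace(counts.mean(axis=0).min(),
                               counts.mean(axis=0).max(), 5):
            k = np.arange(int(lam + 15 * np.sqrt(lam)))
            logp = st.poisson.logpmf(k, lam)
            s_bits = -logp / np.log(2) + (np.exp(logp) * logp).sum() / np.log(2)
            p_cell = max(p_cell, np.exp(logp)[s_bits > 2.0].sum())
        p_trial = 1.0 - st.binom.cdf(1, 12, p_cell)
        se = np.sqrt(p_trial * (1 - p_trial) / len(tr))
        observed = len(rep.removed_trials) / len(tr)
        # model-estimation noise inflates the rate slightly; 4 SE headroom
        assert observed < p_trial + 4 * se
        assert len(rep.removed_units) == 0

    def test_unit_with_inflated_rates_removed(self, clean_counts):
        tr, counts = clean_counts
        rng = np.random.default_rng(16)
        c = counts.copy()
        bad = rng.choice(len(tr), size=60, replace=False)   # 20% of trials
        c[bad, 3] = rng.poisson(
            5 * np.maximum(inverse_anscombe(anscombe(c[bad, 3])), 1.0))
        fit = CleanupModel(anscombe(c), tr).fit()
        rep = detect_outliers(anscombe(c), fit, counts=c)
        assert 3 in rep.removed_units

    def test_single_extreme_count_masked_not_unit_removed(self, clean_counts):
        tr, counts = clean_counts
        c = counts.copy()
        c[50, 2] = 10 * max(c[50, 2], 20.0)
        fit = CleanupModel(anscombe(c), tr).fit()
        rep = detect_outliers(anscombe(c), fit, counts=c)
        assert [50, 2] in rep.masked_cells.tolist()
        assert 2 not in rep.removed_units

    def test_loop_terminates_and_removals_monotone(self, clean_counts):
        tr, counts = clean_counts
        cleaned, fit, reports = iterate_cleanup(anscombe(counts), tr,
                                                counts=counts)
        assert len(reports) <= 10
        assert reports[-1].n_removed == 0   # loop converged


class TestExclusions:
    def test_rules_fire_per_unit(self):
        rng = np.random.default_rng(17)
        n = 200
        tr = od.gen_trial_schedule(n, seed=17)
        tr["choice"] = rng.choice([-1, 1], n)
        low = rng.poisson(2.0, n)                       # below 4 spikes/trial
        over = rng.poisson(rng.gamma(10, 2.0, n))       # Fano ~ 3
        good = rng.poisson(20.0, n)
        counts = np.column_stack([low, over, good]).astype(float)
        r = anscombe(counts)
        fit = CleanupModel(r, tr).fit()
        report = apply_exclusions(counts, r, fit,
                                  circular_variance=np.array([0.2, 0.2, 0.2]))
        assert not report.loc[0, "retained"]
        assert "min_mean_count" in report.loc[0, "rules_fired"]
        assert not report.loc[1, "retained"]
        assert "max_residual_fano" in report.loc[1, "rules_fired"]
        assert report.loc[2, "retained"]

    def test_high_circular_variance_excluded(self):
        rng = np.random.default_rng(18)
        n = 150
        tr = od.gen_trial_schedule(n, seed=18)
        tr["choice"] = rng.choice([-1, 1], n)
        counts = rng.poisson(20.0, (n, 2)).astype(float)
        r = anscombe(counts)
        fit = CleanupModel(r, tr).fit()
        report = apply_exclusions(counts, r, fit,
                                  circular_variance=np.array([0.9, 0.1]))
        assert not report.loc[0, "retained"]
        assert report.loc[1, "retained"]
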