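"""Variance stabilization, the latent-drift data-cleanup model, and outlier
removal for population spike counts.

Spike counts are Anscombe transformed (r = 2·sqrt(count + 3/8)), which
stabilizes Poisson variance to ≈1 and justifies a Gaussian noise model on the
transformed scale.  Each unit's transformed responses are then described by a
data-cleanup model

    r_t = b + x_t·w_x + f^task(s_t) + c_t·w_c + eps_t,

with a squared-exponential GP prior over wall time on the slow drift x
(timescale 120 s) and GP priors over percent signal on the task tuning
functions f^A, f^B, tied at f^A(0) = f^B(0).  The model is fitted by
variational Bayes EM under a structured mean-field factorization
q(x)·q(f); the ELBO is nondecreasing across iterations by construction.

Model predictions converted back to expected spike counts (via the unbiased
inverse Anscombe transform) drive Poisson-surprisal outlier detection: trials
where ≥10% of units exceed 2 bits are dropped, units exceeding 2 bits on ≥10%
of trials are dropped, and individual cells beyond 8 bits are masked.
Finally the best estimate of the slow drift, x̂·w_x, is subtracted from the
responses; tuning and choice terms are left in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .population import sq_exp_kernel

__all__ = [
    "anscombe", "inverse_anscombe", "surprisal_bits",
    "CleanupConfig", "CleanupModel", "CleanupResults",
    "OutlierReport", "detect_outliers", "clean_responses",
    "ExclusionCriteria", "apply_exclusions", "iterate_cleanup",
]


# -- variance stabilization ---------------------------------------------------

_INV_ANSCOMBE_R_CUTOFF = 2.0 * np.sqrt(3.0 / 8.0)


def anscombe(count):
    """Anscombe transform r = 2·sqrt(count + 3/8)."""
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be nonnegative")
    out = 2.0 * np.sqrt(count + 3.0 / 8.0)
    return float(out) if out.ndim == 0 else out


def inverse_anscombe(r):
    """Unbiased inverse of the Anscombe transform (expected Poisson count).

    E[count] ≈ r²/4 − 1/8 + (1/4)·sqrt(3/2)·r⁻¹ − (11/8)·r⁻² +
    (5/8)·sqrt(3/2)·r⁻³.  Values of r at or below the count-zero image
    2·sqrt(3/8) return 0 (with a warning for clearly out-of-domain input).
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r < 0.5 * _INV_ANSCOMBE_R_CUTOFF):
        warnings.warn("inverse_anscombe called below the transform's range; "
                      "returning 0 there", RuntimeWarning, stacklevel=2)
    s32 = np.sqrt(1.5)
    with np.errstate(divide="ignore"):
        out = (r ** 2 / 4.0 - 1.0 / 8.0 + 0.25 * s32 / r
               - (11.0 / 8.0) / r ** 2 + (5.0 / 8.0) * s32 / r ** 3)
    out = np.where(r <= _INV_ANSCOMBE_R_CUTOFF, 0.0, np.maximum(out, 0.0))
    return float(out[0]) if scalar else out


def _poisson_entropy_bits(rate: float) -> float:
    """Exact Poisson entropy in bits, by summation over the support."""
    if rate <= 0:
        raise ValueError("expected_rate must be positive")
    hi = int(np.ceil(rate + 12.0 * np.sqrt(rate) + 30.0))
    k = np.arange(hi + 1)
    logp = stats.poisson.logpmf(k, rate)
    p = np.exp(logp)
    return float(-np.sum(p * logp) / np.log(2.0))


def surprisal_bits(count, expected_rate):
    """Poisson surprisal in bits: −log2 P(count|rate) − entropy(rate).

    Centered so that its expectation is 0 for Poisson data at any rate; the
    distribution of surprisal values is approximately rate-invariant, making a
    fixed bit threshold a rate-invariant outlier score.
    """
    count = np.asarray(count)
    rate = np.asarray(expected_rate, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("expected_rate must be positive")
    nll_bits = -stats.poisson.logpmf(count, rate) / np.log(2.0)
    # entropy computed once per unique rate (rates repeat heavily in practice)
    uniq, inv = np.unique(np.atleast_1d(rate), return_inverse=True)
    ent_u = np.array([_poisson_entropy_bits(v) for v in uniq])
    ent = ent_u[inv].reshape(np.shape(rate)) if np.ndim(rate) else ent_u[inv][0]
    out = nll_bits - ent
    return float(out) if out.ndim == 0 else out


# -- the data-cleanup model ---------------------------------------------------


@dataclass(frozen=True)
class CleanupConfig:
    drift_timescale_s: float = 120.0
    drift_variance: float = 1.0
    tuning_lengthscale: float = 25.0   # percent signal
    tuning_variance: float = 1.0
    max_iter: int = 50
    elbo_tol: float = 1e-6
    jitter: float = 1e-6
    init_drift_loading: float = 0.5


def _tuning_nodes(trials: pd.DataFrame):
    """Unique (task, signal) nodes with the zero-signal node shared.

    Returns (node_signal, node_task, trial_node_index); node_task is "both"
    for the shared s = 0 node.
    """
    s = trials["signal_s"].to_numpy(float)
    task = trials["task"].to_numpy()
    keys = [("both", 0.0) if v == 0.0 else (t, float(v))
            for t, v in zip(task, s)]
    uniq = sorted(set(keys))
    index = {k: i for i, k in enumerate(uniq)}
    node_of_trial = np.array([index[k] for k in keys], dtype=int)
    node_task = np.array([k[0] for k in uniq])
    node_signal = np.array([k[1] for k in uniq])
    return node_signal, node_task, node_of_trial


def _tuning_prior_cov(node_signal, node_task, cfg: CleanupConfig) -> np.ndarray:
    """Joint GP prior over tuning nodes with f^A(0) = f^B(0) shared.

    Within a task: SE kernel k(s, s').  Across tasks the functions are
    conditionally independent given the shared value at s = 0, giving cross
    covariance k(s,0)·k(0,s')/k(0,0).
    """
    def k(a, b):
        return cfg.tuning_variance * np.exp(
            -0.5 * ((a - b) / cfg.tuning_lengthscale) ** 2)

    m = len(node_signal)
    cov = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            same = (node_task[i] == node_task[j]
                    or node_task[i] == "both" or node_task[j] == "both")
            if same:
                cov[i, j] = k(node_signal[i], node_signal[j])
            else:
                cov[i, j] = (k(node_signal[i], 0.0) * k(0.0, node_signal[j])
                             / k(0.0, 0.0))
    return cov + cfg.jitter * np.eye(m)


class CleanupModel:
    """Latent-drift data-cleanup model for a session's response matrix.

    Parameters
    ----------
    r : (trials, units) Anscombe-scale responses; NaN marks masked cells.
    trials : trial table with wall_time_s, task, signal_s, choice columns.
    config : CleanupConfig.

    The model is fitted independently per unit (the latent drift is a per-unit
    posterior; a shared physiological drift shows up as correlated per-unit
    estimates).  :meth:`fit` runs VBEM to convergence of the evidence lower
    bound and returns a :class:`CleanupResults`.
    """

    def __init__(self, r: np.ndarray, trials: pd.DataFrame,
                 config: CleanupConfig | None = None):
        r = np.asarray(r, dtype=float)
        if r.ndim != 2 or r.shape[0] != len(trials):
            raise ValueError("r must be (trials, units) aligned with trials")
        if len(trials) < 100:
            raise ValueError("need >= 100 trials to fit the cleanup model")
        self.r = r
        self.trials = trials.reset_index(drop=True)
        self.config = config or CleanupConfig()

        t = self.trials["wall_time_s"].to_numpy(float)
        kx = sq_exp_kernel(t, self.config.drift_timescale_s,
                           self.config.drift_variance,
                           jitter=self.config.jitter)
        self._sx, self._ux = np.linalg.eigh(kx)   # K_x = U S Uᵀ
        self._sx = np.maximum(self._sx, 1e-12)

        ns, nt, node_of_trial = _tuning_nodes(self.trials)
        self.node_signal, self.node_task = ns, nt
        self.node_of_trial = node_of_trial
        kf = _tuning_prior_cov(ns, nt, self.config)
        self._kf = kf
        self._kf_inv = np.linalg.inv(kf)
        self._kf_logdet = float(np.linalg.slogdet(kf)[1])

    # -- per-unit VBEM -------------------------------------------------------

    def _fit_unit(self, r_u: np.ndarray):
        cfg = self.config
        obs = np.isfinite(r_u)
        c = self.trials["choice"].to_numpy(float)
        node = self.node_of_trial
        m = len(self.node_signal)
        n_obs = int(obs.sum())
        if n_obs < 50:
            raise ValueError("too few unmasked trials for a unit")

        # Missing cells are handled by zero-weighting them everywhere.
        w_obs = obs.astype(float)
        U, S = self._ux, self._sx

        b = float(np.nanmean(r_u))
        wx = cfg.init_drift_loading
        wc = 0.0
        sig2 = max(float(np.nanvar(r_u)), 1e-3)
        mu_x = np.zeros(len(r_u))
        var_x = np.full(len(r_u), cfg.drift_variance)
        mu_g = np.zeros(m)
        sig_g = self._kf.copy()
        r_filled = np.where(obs, r_u, 0.0)

        A_counts = np.zeros(m)
        for j, w in zip(node, w_obs):
            A_counts[j] += w

        all_observed = bool(obs.all())
        elbos = []
        prev = -np.inf
        for _ in range(cfg.max_iter):
            # ---- E-step: q(x) ----
            # Precision = K_x^-1 + (wx^2/sig2) * diag(w_obs).  With no masked
            # cells the diagonal is isotropic and the precomputed eigenbasis
            # of K_x gives the update in O(n^2); otherwise solve densely.
            alpha = wx ** 2 / sig2
            resid_x = w_obs * (r_filled - b - mu_g[node] - c * wc)
            rhs_x = resid_x * (wx / sig2)
            if all_observed:
                s_eff = 1.0 / (1.0 / S + alpha)
                mu_x = U @ (s_eff * (U.T @ rhs_x))
                var_x = (U ** 2) @ s_eff
                kl_terms = (np.sum(s_eff / S), np.sum(np.log(s_eff)))
            else:
                prec_x = (U * (1.0 / S)) @ U.T + alpha * np.diag(w_obs)
                sig_x = np.linalg.inv(prec_x)
                mu_x = sig_x @ rhs_x
                var_x = np.diag(sig_x).copy()
                kl_terms = (np.sum(((U.T @ sig_x) * U.T).sum(axis=1) / S),
                            float(np.linalg.slogdet(sig_x)[1]))

            # ---- E-step: q(g) ----
            resid_g = w_obs * (r_filled - b - wx * mu_x - c * wc)
            rg = np.zeros(m)
            np.add.at(rg, node, resid_g)
            prec_g = self._kf_inv + np.diag(A_counts) / sig2
            sig_g = np.linalg.inv(prec_g)
            mu_g = sig_g @ (rg / sig2)

            # ---- M-step: (b, wx, wc), then sig2 ----
            ex = mu_x
            f_t = mu_g[node]
            y = r_filled - f_t
            w = w_obs
            M = np.array([
                [w.sum(), (w * ex).sum(), (w * c).sum()],
                [(w * ex).sum(), (w * (ex ** 2 + var_x)).sum(),
                 (w * ex * c).sum()],
                [(w * c).sum(), (w * ex * c).sum(), (w * c * c).sum()],
            ])
            rhs3 = np.array([(w * y).sum(), (w * ex * y).sum(),
                             (w * c * y).sum()])
            b, wx, wc = np.linalg.solve(M + 1e-10 * np.eye(3), rhs3)

            mean_resid = w_obs * (r_filled - b - wx * mu_x - f_t - c * wc)
            var_f_t = sig_g[node, node]
            ess = (np.sum(mean_resid ** 2)
                   + wx ** 2 * np.sum(w_obs * var_x)
                   + np.sum(w_obs * var_f_t))
            sig2 = max(ess / n_obs, 1e-8)

            # ---- ELBO ----
            e_lik = -0.5 * n_obs * np.log(2 * np.pi * sig2) - 0.5 * ess / sig2
            # KL(q(x) || p(x)) using the eigenbasis of K_x
            mu_u = U.T @ mu_x
            tr_kinv_sig, logdet_sig_x = kl_terms
            kl_x = 0.5 * (tr_kinv_sig + np.sum(mu_u ** 2 / S)
                          - len(r_u) + np.sum(np.log(S)) - logdet_sig_x)
            sign, logdet_sig_g = np.linalg.slogdet(sig_g)
            kl_g = 0.5 * (np.trace(self._kf_inv @ sig_g)
                          + mu_g @ self._kf_inv @ mu_g - m
                          + self._kf_logdet - logdet_sig_g)
            elbo = float(e_lik - kl_x - kl_g)
            elbos.append(elbo)
            tol = self.config.elbo_tol * (1.0 + abs(elbo))
            if elbo < prev - tol:
                raise RuntimeError(
                    "ELBO decreased beyond tolerance during VBEM: "
                    f"trace={elbos}")
            if abs(elbo - prev) < tol:
                break
            prev = elbo

        return dict(b=b, wx=wx, wc=wc, sig2=sig2, mu_x=mu_x, var_x=var_x,
                    mu_g=mu_g, sig_g=sig_g, elbo_trace=np.array(elbos))

    def fit(self) -> "CleanupResults":
        units = []
        for i in range(self.r.shape[1]):
            units.append(self._fit_unit(self.r[:, i]))
        return CleanupResults(self, units)


class CleanupResults:
    """Per-unit VBEM fits of the data-cleanup model."""

    def __init__(self, model: CleanupModel, units: list):
        self.model = model
        self._units = units
        n, p = model.r.shape
        self.baseline = np.array([u["b"] for u in units])
        self.drift_loading = np.array([u["wx"] for u in units])
        self.choice_loading = np.array([u["wc"] for u in units])
        self.noise_variance = np.array([u["sig2"] for u in units])
        self.xhat = np.column_stack([u["mu_x"] for u in units])
        self.xhat_var = np.column_stack([u["var_x"] for u in units])
        self.tuning_mean = np.column_stack([u["mu_g"] for u in units])
        self.elbo_traces = [u["elbo_trace"] for u in units]

    @property
    def drift_component(self) -> np.ndarray:
        """x̂·w_x per trial and unit — the slow-fluctuation estimate that
        :func:`clean_responses` subtracts."""
        return self.xhat * self.drift_loading[None, :]

    def predicted_r(self) -> np.ndarray:
        """Posterior-mean model prediction of r per trial and unit."""
        node = self.model.node_of_trial
        c = self.model.trials["choice"].to_numpy(float)[:, None]
        return (self.baseline[None, :] + self.drift_component
                + self.tuning_mean[node, :]
                + c * self.choice_loading[None, :])

    def tuning_curve(self, unit: int, task: str):
        """(signal grid, posterior-mean tuning) for one unit and task."""
        sel = (self.model.node_task == task) | (self.model.node_task == "both")
        return (self.model.node_signal[sel], self.tuning_mean[sel, unit])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "baseline": self.baseline,
            "drift_loading": self.drift_loading,
            "choice_loading": self.choice_loading,
            "noise_variance": self.noise_variance,
            "elbo": [t[-1] for t in self.elbo_traces],
            "n_iter": [len(t) for t in self.elbo_traces],
        })


# -- outlier detection and cleaning ------------------------------------------


@dataclass
class OutlierReport:
    removed_trials: np.ndarray
    removed_units: np.ndarray
    masked_cells: np.ndarray          # (k, 2) of (trial, unit)
    surprisal: np.ndarray             # (trials, units) bits (NaN where masked)

    @property
    def n_removed(self) -> int:
        return (len(self.removed_trials) + len(self.removed_units)
                + len(self.masked_cells))


def detect_outliers(r: np.ndarray, fit: CleanupResults,
                    counts: np.ndarray | None = None,
                    trial_bit_threshold: float = 2.0,
                    cell_bit_threshold: float = 8.0,
                    frac_threshold: float = 0.10) -> OutlierReport:
    """Apply the three surprisal rules against the cleanup-model predictions.

    In order: trials where at least ``frac_threshold`` of units exceed
    ``trial_bit_threshold`` bits are removed; units exceeding it on at least
    ``frac_threshold`` of trials are removed; remaining single cells beyond
    ``cell_bit_threshold`` bits are masked.  Expected rates come from the
    unbiased inverse Anscombe transform of the model predictions.
    """
    r = np.asarray(r, dtype=float)
    obs = np.isfinite(r)
    if counts is None:
        counts = np.round(np.where(obs, r, 0.0) ** 2 / 4.0 - 3.0 / 8.0)
        counts = np.maximum(counts, 0.0)
    pred = fit.predicted_r()
    rate = np.maximum(inverse_anscombe(
        np.maximum(pred, _INV_ANSCOMBE_R_CUTOFF + 1e-6)), 1e-3)
    bits = np.full(r.shape, np.nan)
    bits[obs] = surprisal_bits(counts[obs], rate[obs])

    surprising = (bits > trial_bit_threshold) & obs
    frac_units = surprising.sum(axis=1) / np.maximum(obs.sum(axis=1), 1)
    bad_trials = np.flatnonzero(frac_units >= frac_threshold)

    keep_t = np.setdiff1d(np.arange(r.shape[0]), bad_trials)
    frac_trials = (surprising[keep_t].sum(axis=0)
                   / np.maximum(obs[keep_t].sum(axis=0), 1))
    bad_units = np.flatnonzero(frac_trials >= frac_threshold)

    cell_mask = (bits > cell_bit_threshold) & obs
    cell_mask[bad_trials, :] = False
    cell_mask[:, bad_units] = False
    cells = np.argwhere(cell_mask)

    if len(bad_trials) == r.shape[0]:
        raise RuntimeError("all trials flagged as outliers; degenerate session")
    return OutlierReport(removed_trials=bad_trials, removed_units=bad_units,
                         masked_cells=cells, surprisal=bits)


def clean_responses(r: np.ndarray, fit: CleanupResults) -> np.ndarray:
    """Subtract the slow-drift estimate: r − x̂·w_x (tuning and choice terms
    are deliberately left in).  Masked (NaN) cells stay masked."""
    return np.asarray(r, float) - fit.drift_component


def iterate_cleanup(r: np.ndarray, trials: pd.DataFrame,
                    config: CleanupConfig | None = None,
                    counts: np.ndarray | None = None,
                    max_loops: int = 10):
    """The fit → detect → exclude loop, capped at ``max_loops`` iterations.

    Returns (cleaned responses, final fit, list of per-iteration reports).
    Removed trials/units are masked (NaN), so removals are monotone.
    """
    r = np.asarray(r, dtype=float).copy()
    reports = []
    fit = None
    for _ in range(max_loops):
        fit = CleanupModel(r, trials, config).fit()
        rep = detect_outliers(r, fit, counts=counts)
        reports.append(rep)
        if rep.n_removed == 0:
            break
        r[rep.removed_trials, :] = np.nan
        r[:, rep.removed_units] = np.nan
        if len(rep.masked_cells):
            r[rep.masked_cells[:, 0], rep.masked_cells[:, 1]] = np.nan
    return clean_responses(r, fit), fit, reports


# -- unit exclusions ----------------------------------------------------------


@dataclass(frozen=True)
class ExclusionCriteria:
    min_mean_count: float = 4.0
    max_residual_fano: float = 2.0
    min_variance: float = 0.1
    max_circular_variance: float = 0.8


def apply_exclusions(counts: np.ndarray, cleaned_r: np.ndarray,
                     fit: CleanupResults,
                     circular_variance: np.ndarray | None = None,
                     criteria: ExclusionCriteria | None = None,
                     ) -> pd.DataFrame:
    """Drop unreliable or untuned units.

    A unit fails if its mean count is below 4 spikes/trial, its residual Fano
    factor (variance of count residuals about the model prediction over mean
    count) exceeds 2, its Anscombe-scale response variance is below 0.1, or
    its grating circular variance exceeds 0.8.  Returns one row per unit with
    ``retained`` and the rule(s) that fired.
    """
    crit = criteria or ExclusionCriteria()
    counts = np.asarray(counts, float)
    cleaned_r = np.asarray(cleaned_r, float)
    pred_counts = inverse_anscombe(
        np.maximum(fit.predicted_r(), _INV_ANSCOMBE_R_CUTOFF + 1e-6))
    p = counts.shape[1]
    rows = []
    for i in range(p):
        obs = np.isfinite(cleaned_r[:, i]) & np.isfinite(counts[:, i])
        mean_count = counts[obs, i].mean() if obs.any() else 0.0
        resid = counts[obs, i] - pred_counts[obs, i]
        fano = resid.var(ddof=1) / max(mean_count, 1e-12) if obs.sum() > 2 else np.inf
        var_r = np.nanvar(cleaned_r[obs, i]) if obs.any() else 0.0
        cv = (circular_variance[i] if circular_variance is not None else np.nan)
        fired = []
        if mean_count < crit.min_mean_count:
            fired.append("min_mean_count")
        if fano > crit.max_residual_fano:
            fired.append("max_residual_fano")
        if var_r < crit.min_variance:
            fired.append("min_variance")
        if np.isfinite(cv) and cv > crit.max_circular_variance:
            fired.append("max_circular_variance")
        rows.append({"unit": i, "mean_count": mean_count,
                     "residual_fano": fano, "variance": var_r,
                     "circular_variance": cv,
                     "retained": not fired, "rules_fired": ",".join(fired)})
    return pd.DataFrame(rows)
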