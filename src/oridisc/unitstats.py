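"""Orientation tuning, task sensitivity (f′, d′), choice probability, and a
regularized population choice decoder.

Conventions: a unit's task-tuning slope f′ is the regression slope of its
(Anscombe-scale, drift-cleaned) response on λ_f·tanh(s/λ_f), estimated from
trials with |s| > 5.67% signal; its private noise σ comes from low-signal
(≤ 5.67%) residuals, so the two estimates never share trials.  Neural
sensitivity is d′ = 50·f′/σ (extrapolating to ±50% signal).  Choice
probability is the signed exceedance probability (ties counted ½) between
per-signal-level mean-subtracted responses on the two choices; CP > 0.5 means
higher responses predict the positive choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "TuningCurveFit", "fit_orientation_tuning",
    "estimate_fprime", "compute_dprime",
    "CPResult", "compute_cp", "DecoderResult", "decode_choice",
    "FPRIME_MIN_SIGNAL", "CP_MAX_SIGNAL",
]

FPRIME_MIN_SIGNAL = 5.67    # |s| strictly above this is the f' trial set
CP_MAX_SIGNAL = 20.0        # CP pools residuals up to +/- this signal
_CP_MIN_TRIALS_PER_LEVEL = 20


# -- orientation tuning -------------------------------------------------------


@dataclass
class TuningCurveFit:
    preferred_deg: float              # mod 180
    preferred_boot: np.ndarray        # bootstrap distribution (n_boot,)
    circular_variance: float
    vm_amplitude: float
    vm_kappa: float
    vm_offset: float


def _weighted_circular_mean_deg(orientations_deg, weights) -> float:
    """Response-weighted circular mean of orientations (doubled-angle)."""
    ang = np.radians(2.0 * np.asarray(orientations_deg, float))
    w = np.asarray(weights, float)
    z = np.sum(w * np.exp(1j * ang))
    return float(np.degrees(np.angle(z)) / 2.0 % 180.0)


def fit_orientation_tuning(orientations_deg: np.ndarray,
                           responses: np.ndarray,
                           baseline_subtracted: np.ndarray | None = None,
                           n_boot: int = 500, seed: int = 0) -> TuningCurveFit:
    """Fit a unit's orientation tuning from grating trials.

    ``orientations_deg`` (per trial, collapsed to 180°) and ``responses``
    (Anscombe-transformed counts) drive the von Mises least-squares fit and
    the weighted circular mean (angles doubled, averaged, halved).  Circular
    variance is computed on ``baseline_subtracted`` rates when given (not
    subtracting the baseline inflates circular variance), clipped at 0.
    """
    ori = np.asarray(orientations_deg, float) % 180.0
    resp = np.asarray(responses, float)
    if np.all(resp == 0):
        raise ValueError("all-zero responses: preferred orientation undefined")
    rng = np.random.default_rng(seed)

    pref = _weighted_circular_mean_deg(ori, np.maximum(resp, 0.0))
    boot = np.empty(n_boot)
    n = len(ori)
    for k in range(n_boot):
        idx = rng.integers(0, n, n)
        boot[k] = _weighted_circular_mean_deg(ori[idx],
                                              np.maximum(resp[idx], 0.0))

    cv_resp = resp if baseline_subtracted is None else \
        np.asarray(baseline_subtracted, float)
    w = np.maximum(cv_resp, 0.0)
    ang = np.radians(2.0 * ori)
    tot = np.sum(w)
    circ_var = 1.0 if tot <= 0 else float(
        1.0 - np.abs(np.sum(w * np.exp(1j * ang))) / tot)

    def vm(theta, amp, mu, kappa, off):
        return off + amp * np.exp(kappa * (np.cos(np.radians(2 * (theta - mu)))
                                           - 1.0))

    try:
        popt, _ = optimize.curve_fit(
            vm, ori, resp,
            p0=[resp.max() - resp.min() + 1e-6, pref, 1.0, resp.min()],
            maxfev=5000)
        amp, _, kappa, off = popt
    except RuntimeError:   # fit failure: report moments only
        amp, kappa, off = np.nan, np.nan, np.nan
    return TuningCurveFit(preferred_deg=pref, preferred_boot=boot,
                          circular_variance=circ_var, vm_amplitude=float(amp),
                          vm_kappa=float(kappa), vm_offset=float(off))


# -- sensitivity --------------------------------------------------------------


def estimate_fprime(r: np.ndarray, signal_s: np.ndarray,
                    lambda_f: float = 30.0, n_boot: int = 500, seed: int = 0,
                    min_signal: float = FPRIME_MIN_SIGNAL,
                    min_trials: int = 25) -> tuple[float, np.ndarray]:
    """Tuning slope at s = 0 per percent signal, with bootstrap.

    Least-squares slope of r on λ_f·tanh(s/λ_f) using only trials with
    |s| > ``min_signal``; the tanh rescaling linearizes saturating tuning so
    the slope extrapolates the s = 0 derivative.  Returns (f′, bootstrap
    samples of f′).
    """
    r = np.asarray(r, float)
    s = np.asarray(signal_s, float)
    keep = (np.abs(s) > min_signal) & np.isfinite(r)
    if keep.sum() < min_trials:
        raise ValueError(f"only {int(keep.sum())} trials above "
                         f"{min_signal}% signal (need >= {min_trials})")
    x = lambda_f * np.tanh(s[keep] / lambda_f)
    y = r[keep]

    def slope(xv, yv):
        xc = xv - xv.mean()
        return float(xc @ (yv - yv.mean()) / (xc @ xc))

    fp = slope(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    boot = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, n)
        boot[k] = slope(x[idx], y[idx])
    return fp, boot


def compute_dprime(fprime: float, sigma: float) -> float:
    """Neural sensitivity d′ = 50·f′/σ (σ the private low-signal noise SD)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 50.0 * fprime / sigma


# -- choice probability -------------------------------------------------------


@dataclass
class CPResult:
    cp: float
    boot: np.ndarray
    ci_lo: float
    ci_hi: float
    significant: bool
    n_trials: int


def _exceedance(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(sample from pos > sample from neg), ties counted one-half."""
    # Rank-based evaluation: identical to the normalized Mann-Whitney U.
    from scipy.stats import rankdata
    comb = np.concatenate([pos, neg])
    ranks = rankdata(comb)
    r_pos = ranks[:len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def compute_cp(r: np.ndarray, trials: pd.DataFrame, n_boot: int = 500,
               seed: int = 0, max_signal: float = CP_MAX_SIGNAL,
               min_trials_per_level: int = _CP_MIN_TRIALS_PER_LEVEL,
               alpha: float = 0.05) -> CPResult:
    """Signed choice probability of one unit with bootstrap significance.

    Mean response per unique signal level is subtracted, residuals pooled
    over levels with |s| ≤ ``max_signal`` and at least
    ``min_trials_per_level`` trials, and CP computed as the exceedance
    probability of positive-choice over negative-choice residuals.
    Significance is two-sided from the bootstrap CDF at ``alpha``.
    """
    r = np.asarray(r, float)
    s = trials["signal_s"].to_numpy(float)
    c = trials["choice"].to_numpy()
    ok = np.isfinite(r) & (np.abs(s) <= max_signal) & np.isin(c, (-1, 1))

    resid, choice = [], []
    for level in np.unique(s[ok]):
        m = ok & (s == level)
        if m.sum() < min_trials_per_level:
            continue
        resid.append(r[m] - r[m].mean())
        choice.append(c[m])
    if not resid:
        raise ValueError("no signal level passes the trial-count rule")
    resid = np.concatenate(resid)
    choice = np.concatenate(choice)
    pos, neg = resid[choice == 1], resid[choice == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("one choice class empty: CP undefined for this unit")

    cp = _exceedance(pos, neg)
    rng = np.random.default_rng(seed)
    n = len(resid)
    boot = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, n)
        rb, cb = resid[idx], choice[idx]
        pb, nb = rb[cb == 1], rb[cb == -1]
        boot[k] = _exceedance(pb, nb) if len(pb) and len(nb) else 0.5
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    tail = min(np.mean(boot <= 0.5), np.mean(boot >= 0.5))
    return CPResult(cp=cp, boot=boot, ci_lo=float(lo), ci_hi=float(hi),
                    significant=bool(2 * tail < alpha), n_trials=n)


# -- population choice decoder ------------------------------------------------


@dataclass
class DecoderResult:
    accuracy: float
    fold_accuracy: np.ndarray
    shuffle_accuracy: float
    n_folds: int


def decode_choice(r: np.ndarray, labels: np.ndarray, n_folds: int = 10,
                  shrinkage: float | str = "auto", seed: int = 0,
                  ) -> DecoderResult:
    """Held-out choice decoding with shrinkage-regularized LDA.

    Stratified K-fold accuracy of an LDA decoder (lsqr solver with
    Ledoit-Wolf ``"auto"`` shrinkage by default), reported alongside a
    label-shuffle control run through the identical pipeline.
    """
    r = np.asarray(r, float)
    labels = np.asarray(labels)
    ok = np.all(np.isfinite(r), axis=1)
    r, labels = r[ok], labels[ok]
    if n_folds < 2:
        raise ValueError("need >= 2 folds")
    frac = np.mean(labels == labels[0])
    if max(frac, 1 - frac) > 0.95:
        import warnings
        warnings.warn("severe class imbalance (> 95/5); decoding accuracy "
                      "is dominated by the majority class", RuntimeWarning,
                      stacklevel=2)

    def cv_accuracy(y, rng):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        accs = []
        for tr, te in skf.split(r, y):
            clf = LinearDiscriminantAnalysis(solver="lsqr",
                                             shrinkage=shrinkage)
            clf.fit(r[tr], y[tr])
            accs.append(float(np.mean(clf.predict(r[te]) == y[te])))
        return np.array(accs)

    rng = np.random.default_rng(seed)
    folds = cv_accuracy(labels, rng)
    shuffled = rng.permutation(labels)
    sh = cv_accuracy(shuffled, rng)
    return DecoderResult(accuracy=float(folds.mean()), fold_accuracy=folds,
                         shuffle_accuracy=float(sh.mean()), n_folds=n_folds)
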