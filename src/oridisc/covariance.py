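"""Regularized noise-covariance estimation and task-dependence tests.

Noise covariance is estimated from per-signal-level mean-subtracted residuals
on low-signal (|s| ≤ 5.67%) trials, with the diagonal regularizer
C = R̂ ⊙ σ̂σ̂ᵀ: sample correlations shrunk toward the identity by λ_R and
per-unit variances shrunk toward the median variance by λ_σ (defaults 0.6 and
0.1).  Three task-dependence analyses follow: a cross-validated Gaussian
log-likelihood switching test (100 folds per task), the f′-projection
variance test (bootstrap variance along each task's decoding axis under each
task's covariance), and limited-range / decision-pool correlation structure
versus difference in preferred orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LOW_SIGNAL_COV_MAX", "residuals_per_level", "regularize_covariance",
    "CovarianceEstimate", "cv_gaussian_loglik", "switching_test",
    "SwitchScoreSet", "fprime_projection_test", "ProjectionVarianceResult",
    "limited_range_analysis", "pool_comparison",
]

LOW_SIGNAL_COV_MAX = 5.67     # |s| <= this defines the covariance trial set
_MIN_TRIALS_FLOOR = 20
_MIN_TRIALS_PER_LEVEL = 5


@dataclass
class CovarianceEstimate:
    C: np.ndarray
    lambda_R: float
    lambda_sigma: float
    n_trials: int

    def __post_init__(self) -> None:
        # PSD check: the regularized estimate must admit a Cholesky factor.
        np.linalg.cholesky(self.C + 1e-12 * np.eye(len(self.C)))


def residuals_per_level(r: np.ndarray, signal_s: np.ndarray,
                        max_abs_signal: float = LOW_SIGNAL_COV_MAX,
                        min_trials_per_level: int = _MIN_TRIALS_PER_LEVEL,
                        ) -> np.ndarray:
    """Per-signal-level mean-subtracted responses on low-signal trials.

    Levels with fewer than ``min_trials_per_level`` trials are dropped.
    """
    r = np.asarray(r, float)
    s = np.asarray(signal_s, float)
    ok = (np.abs(s) <= max_abs_signal) & np.all(np.isfinite(r), axis=1)
    chunks = []
    for level in np.unique(s[ok]):
        m = ok & (s == level)
        if m.sum() < min_trials_per_level:
            continue
        chunks.append(r[m] - r[m].mean(axis=0))
    if not chunks:
        raise ValueError("no usable low-signal level")
    return np.vstack(chunks)


def regularize_covariance(residuals: np.ndarray, lambda_R: float = 0.6,
                          lambda_sigma: float = 0.1) -> CovarianceEstimate:
    """Diagonal-regularized covariance of mean-subtracted residuals.

    R̂ = R(1−λ_R) + I·λ_R and σ̂ᵢ² = σᵢ²(1−λ_σ) + median(σ²)·λ_σ (the median
    is taken over the per-unit variances), then C = R̂ ⊙ σ̂σ̂ᵀ.
    """
    x = np.asarray(residuals, float)
    if x.shape[0] < _MIN_TRIALS_FLOOR:
        raise ValueError(f"need >= {_MIN_TRIALS_FLOOR} residual trials")
    cov = np.cov(x, rowvar=False)
    var = np.diag(cov).copy()
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    r_hat = corr * (1.0 - lambda_R) + np.eye(len(var)) * lambda_R
    var_hat = var * (1.0 - lambda_sigma) + np.median(var) * lambda_sigma
    sd_hat = np.sqrt(var_hat)
    c = r_hat * np.outer(sd_hat, sd_hat)
    return CovarianceEstimate(C=c, lambda_R=lambda_R,
                              lambda_sigma=lambda_sigma, n_trials=x.shape[0])


def cv_gaussian_loglik(c_train: np.ndarray, test_residuals: np.ndarray,
                       ) -> float:
    """Per-unit-normalized Gaussian log likelihood of held-out residuals.

    logL = −(1/2N)·[Tr(C_train⁻¹·C_test) + log|C_train|], with C_test the
    biased (1/n) second-moment matrix of the held-out residuals about zero
    (residuals are pre-centered).  Equals −0.5 when both are the identity.
    """
    c_train = np.asarray(c_train, float)
    x = np.atleast_2d(np.asarray(test_residuals, float))
    n_units = c_train.shape[0]
    if x.shape == c_train.shape and np.allclose(x, x.T):
        c_test = x                     # a precomputed test covariance
    else:
        c_test = x.T @ x / x.shape[0]  # biased moment about zero
    sign, logdet = np.linalg.slogdet(c_train)
    if sign <= 0:
        raise np.linalg.LinAlgError("C_train is not positive definite")
    tr = float(np.trace(np.linalg.solve(c_train, c_test)))
    return -0.5 / n_units * (tr + logdet)


@dataclass
class SwitchScoreSet:
    within_ll: dict      # task -> (n_folds,)
    across_ll: dict      # task -> (n_folds,)
    scores: dict         # task -> within − across, paired per fold
    t_pvalue: dict       # task -> one-sided t-test p (scores > 0)


def switching_test(resid_a: np.ndarray, resid_b: np.ndarray,
                   n_folds: int = 100, seed: int = 0,
                   lambda_R: float = 0.6, lambda_sigma: float = 0.1,
                   tasks: tuple = ("A", "B")) -> SwitchScoreSet:
    """Cross-validated log-likelihood switching test between two tasks.

    Each task's (pre-centered) low-signal residuals are split into
    ``n_folds`` folds.  Per fold, the within-task score evaluates the held-out
    residuals under the covariance trained on the same task's remaining
    trials; the across-task score evaluates the identical held-out residuals
    under the other task's training covariance for the paired fold.  The
    paired differences are the switching scores, tested one-sided for > 0.
    """
    rng = np.random.default_rng(seed)
    resid = {tasks[0]: np.asarray(resid_a, float),
             tasks[1]: np.asarray(resid_b, float)}
    for t, x in resid.items():
        if x.shape[0] < n_folds:
            raise ValueError(f"task {t} has fewer trials than folds")
    folds = {t: np.array_split(rng.permutation(x.shape[0]), n_folds)
             for t, x in resid.items()}

    trained = {}
    for t in tasks:
        x = resid[t]
        trained[t] = []
        for k in range(n_folds):
            tr = np.setdiff1d(np.arange(x.shape[0]), folds[t][k])
            trained[t].append(regularize_covariance(
                x[tr], lambda_R, lambda_sigma).C)

    within, across, scores, pvals = {}, {}, {}, {}
    for t, other in ((tasks[0], tasks[1]), (tasks[1], tasks[0])):
        w = np.empty(n_folds)
        a = np.empty(n_folds)
        for k in range(n_folds):
            held = resid[t][folds[t][k]]
            w[k] = cv_gaussian_loglik(trained[t][k], held)
            a[k] = cv_gaussian_loglik(trained[other][k], held)
        within[t], across[t] = w, a
        scores[t] = w - a
        pvals[t] = float(stats.ttest_1samp(scores[t], 0.0,
                                           alternative="greater").pvalue)
    return SwitchScoreSet(within_ll=within, across_ll=across,
                          scores=scores, t_pvalue=pvals)


@dataclass
class ProjectionVarianceResult:
    variances: dict      # (axis task i, cov task j) -> (n_boot,)
    tasks: tuple

    def difference(self, axis_task: str) -> np.ndarray:
        """Bootstrap samples of v_ii − v_ij for a task's own axis."""
        other = self.tasks[1] if axis_task == self.tasks[0] else self.tasks[0]
        return (self.variances[(axis_task, axis_task)]
                - self.variances[(axis_task, other)])

    def tail_fraction(self, axis_task: str) -> float:
        """Fraction of bootstrap differences at or below zero (one tail)."""
        d = self.difference(axis_task)
        return float(np.mean(d <= 0))


def fprime_projection_test(r: np.ndarray, trials: pd.DataFrame,
                           n_boot: int = 500, seed: int = 0,
                           lambda_f: float = 30.0,
                           lambda_R: float = 0.6, lambda_sigma: float = 0.1,
                           ) -> ProjectionVarianceResult:
    """Bootstrap variance along each task's f′ axis under each task's C.

    Per bootstrap repeat, f′ is re-estimated from resampled |s| > 5.67%
    trials and C from resampled |s| ≤ 5.67% trials (disjoint sets by
    construction), and v_ij = f′ᵢᵀ C_j f′ᵢ / ‖f′ᵢ‖² computed for all four
    task combinations.
    """
    from .unitstats import FPRIME_MIN_SIGNAL
    r = np.asarray(r, float)
    s = trials["signal_s"].to_numpy(float)
    task = trials["task"].to_numpy()
    tasks = tuple(sorted(pd.unique(task)))
    if len(tasks) != 2:
        raise ValueError("projection test needs both tasks")
    finite = np.all(np.isfinite(r), axis=1)
    hi = {t: np.flatnonzero((task == t) & (np.abs(s) > FPRIME_MIN_SIGNAL)
                            & finite) for t in tasks}
    lo = {t: np.flatnonzero((task == t) & (np.abs(s) <= LOW_SIGNAL_COV_MAX)
                            & finite) for t in tasks}
    for t in tasks:
        assert len(np.intersect1d(hi[t], lo[t])) == 0
        if len(hi[t]) < 25 or len(lo[t]) < _MIN_TRIALS_FLOOR:
            raise ValueError(f"too few trials for task {t}")

    rng = np.random.default_rng(seed)
    out = {(i, j): np.empty(n_boot) for i in tasks for j in tasks}
    for b in range(n_boot):
        fps, covs = {}, {}
        for t in tasks:
            hidx = rng.choice(hi[t], size=len(hi[t]), replace=True)
            x = lambda_f * np.tanh(s[hidx] / lambda_f)
            xc = x - x.mean()
            fp = (r[hidx] - r[hidx].mean(axis=0)).T @ xc / (xc @ xc)
            nrm = np.linalg.norm(fp)
            if nrm == 0:
                raise ValueError(f"zero-norm f' for task {t}")
            fps[t] = fp / nrm
            lidx = rng.choice(lo[t], size=len(lo[t]), replace=True)
            res = residuals_per_level(r[lidx], s[lidx])
            covs[t] = regularize_covariance(res, lambda_R, lambda_sigma).C
        for i in tasks:
            for j in tasks:
                out[(i, j)][b] = float(fps[i] @ covs[j] @ fps[i])
    return ProjectionVarianceResult(variances=out, tasks=tasks)


# -- limited-range and decision-pool structure --------------------------------


def limited_range_analysis(pair_records: pd.DataFrame, bin_deg: float = 5.0,
                           ) -> pd.DataFrame:
    """Mean noise correlation vs difference in preferred orientation.

    ``pair_records`` holds one row per (pair, bootstrap) with columns
    ``dpref_deg`` (already in [0°, 90°]) and ``correlation``.  Correlations
    are binned by Δpreferred in ``bin_deg`` bins; the SE per bin is the SD of
    the per-bin mean across bootstrap samples (column ``boot``).  Empty bins
    are reported as missing rows, not zeros.
    """
    df = pair_records.copy()
    if np.any(df["dpref_deg"] < 0) or np.any(df["dpref_deg"] > 90):
        raise ValueError("dpref_deg must be folded into [0, 90] degrees")
    edges = np.arange(0.0, 90.0 + bin_deg, bin_deg)
    df["bin"] = pd.cut(df["dpref_deg"], edges, right=False,
                       include_lowest=True)
    rows = []
    for b, grp in df.groupby("bin", observed=True):
        if len(grp) == 0:
            continue
        mean = grp["correlation"].mean()
        if "boot" in grp.columns and grp["boot"].nunique() > 1:
            per_boot = grp.groupby("boot")["correlation"].mean()
            se = per_boot.std(ddof=1)
        else:
            se = grp["correlation"].std(ddof=1) / np.sqrt(len(grp))
        rows.append({"bin_lo": b.left, "bin_hi": b.right,
                     "mean_correlation": mean, "se": se, "n": len(grp)})
    return pd.DataFrame(rows)


def pair_records_from_session(r: np.ndarray, trials: pd.DataFrame,
                              preferred_deg: np.ndarray, n_boot: int = 100,
                              seed: int = 0, lambda_f: float = 30.0,
                              ) -> pd.DataFrame:
    """Bootstrapped pair records for the limited-range and pool analyses.

    Per bootstrap repeat: f′ per task from resampled |s| > 5.67% trials
    (defining decision pools via sign f′ᵢf′ⱼ) and noise correlations per task
    from resampled per-level-centered low-signal residuals.  One row per
    (unit pair, bootstrap) with Δpreferred (folded to [0°, 90°]), per-task
    correlations and pool labels, the pool-switching flag, and — for
    switching pairs — ``corr_same``/``corr_diff`` (correlation in the task
    where the pair shares a pool vs the task where it does not).
    """
    from .unitstats import FPRIME_MIN_SIGNAL
    r = np.asarray(r, float)
    s = trials["signal_s"].to_numpy(float)
    task = trials["task"].to_numpy()
    tasks = tuple(sorted(pd.unique(task)))
    if len(tasks) != 2:
        raise ValueError("pair records need both tasks")
    finite = np.all(np.isfinite(r), axis=1)
    hi = {t: np.flatnonzero((task == t) & (np.abs(s) > FPRIME_MIN_SIGNAL)
                            & finite) for t in tasks}
    lo = {t: np.flatnonzero((task == t) & (np.abs(s) <= LOW_SIGNAL_COV_MAX)
                            & finite) for t in tasks}
    p = r.shape[1]
    iu, ju = np.triu_indices(p, k=1)
    dpref = fold_dpref(preferred_deg[iu], preferred_deg[ju])
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_boot):
        fps, corrs = {}, {}
        for t in tasks:
            hidx = rng.choice(hi[t], size=len(hi[t]), replace=True)
            x = lambda_f * np.tanh(s[hidx] / lambda_f)
            xc = x - x.mean()
            fps[t] = (r[hidx] - r[hidx].mean(axis=0)).T @ xc / (xc @ xc)
            lidx = rng.choice(lo[t], size=len(lo[t]), replace=True)
            res = residuals_per_level(r[lidx], s[lidx])
            corrs[t] = np.corrcoef(res, rowvar=False)
        same = {t: fps[t][iu] * fps[t][ju] > 0 for t in tasks}
        switching = same[tasks[0]] != same[tasks[1]]
        cs = np.where(same[tasks[0]], corrs[tasks[0]][iu, ju],
                      corrs[tasks[1]][iu, ju])
        cd = np.where(same[tasks[0]], corrs[tasks[1]][iu, ju],
                      corrs[tasks[0]][iu, ju])
        rows.append(pd.DataFrame({
            "pair_id": iu * p + ju, "boot": b, "dpref_deg": dpref,
            f"corr_{tasks[0]}": corrs[tasks[0]][iu, ju],
            f"corr_{tasks[1]}": corrs[tasks[1]][iu, ju],
            "correlation": 0.5 * (corrs[tasks[0]][iu, ju]
                                  + corrs[tasks[1]][iu, ju]),
            f"same_pool_{tasks[0]}": same[tasks[0]],
            f"same_pool_{tasks[1]}": same[tasks[1]],
            "pool_switching": switching,
            "corr_same": cs, "corr_diff": cd,
        }))
    return pd.concat(rows, ignore_index=True)


def fold_dpref(pref_i, pref_j):
    """Difference in preferred orientation mod 180°, folded to [0°, 90°]."""
    d = np.abs(np.asarray(pref_i, float) - np.asarray(pref_j, float)) % 180.0
    return np.minimum(d, 180.0 - d)


_DEFAULT_POOL_BINS = ((0.0, 20.0), (20.0, 45.0), (45.0, 90.0))


def pool_comparison(pair_records: pd.DataFrame,
                    bins: tuple = _DEFAULT_POOL_BINS) -> pd.DataFrame:
    """Same-pool minus different-pool correlation among pool-switching pairs.

    Restricted to pairs that are in the same pool (sign f′ᵢf′ⱼ > 0) in one
    task and different pools in the other, so each pair contributes exactly
    once to each pool and compositions are matched by construction.
    ``pair_records`` columns: ``dpref_deg``, ``boot``, ``corr_same``
    (correlation in the task where the pair shares a pool) and ``corr_diff``.
    Significance per Δpref bin is the fraction of bootstrap mean paired
    differences on either side of zero (two-sided, doubled tail).
    """
    df = pair_records
    if len(df) == 0:
        warnings.warn("no pool-switching pairs", RuntimeWarning, stacklevel=2)
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "mean_difference",
                                     "p_value", "n_pairs"])
    rows = []
    for lo, hi in bins:
        m = (df["dpref_deg"] >= lo) & (df["dpref_deg"] < hi)
        grp = df[m]
        if len(grp) == 0:
            continue
        diff = grp["corr_same"] - grp["corr_diff"]
        per_boot = diff.groupby(grp["boot"]).mean()
        tail = min((per_boot <= 0).mean(), (per_boot >= 0).mean())
        rows.append({"bin_lo": lo, "bin_hi": hi,
                     "mean_difference": float(diff.mean()),
                     "p_value": float(2 * tail),
                     "n_pairs": int(grp["pair_id"].nunique()
                                    if "pair_id" in grp else len(grp))})
    return pd.DataFrame(rows)
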