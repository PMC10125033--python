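"""Bayesian errors-in-variables regression with crossed random effects.

Each observation is a noisy measurement (x_obs, y_obs) — with known,
bootstrap-derived measurement SDs — of latent coordinates (x̂, ŷ) tied by a
linear law ŷ = y0 + β̂·(x̂ − x0).  Both coordinates and the slope carry
crossed electrode/session random effects:

    x̂  = x0 + Δx_e + Δx_s + Δx_se
    ŷ  = y0 + Δy_e + Δy_s + Δy_se + β̂·(x̂ − x0)
    β̂  = β + Δβ_e + Δβ_s

Every Δ term is zero-mean Gaussian whose scale has a half-Cauchy prior (width
five times the data SD along the corresponding axis; for slope scales the
ratio of y to x SDs), which shrinks unsupported random effects toward zero.
The joint posterior is sampled by gradient-based HMC in a non-centered
parameterization.  The headline quantity is the effective slope
β_eff = β + mean_s Δβ_s + mean_e Δβ_e per sample, summarized by probability
of direction and a marginal R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmc import sample_hmc

__all__ = ["EIVModel", "EIVResults", "probability_of_direction",
           "marginal_r2"]


@dataclass(frozen=True)
class _Layout:
    n: int
    n_e: int
    n_s: int

    # slices into the parameter vector
    def slices(self):
        idx = {}
        k = 0

        def take(name, size):
            nonlocal k
            idx[name] = slice(k, k + size)
            k += size

        take("beta", 1)
        take("x0", 1)
        take("y0", 1)
        take("eta_x_e", self.n_e)
        take("eta_y_e", self.n_e)
        take("eta_b_e", self.n_e)
        take("eta_x_s", self.n_s)
        take("eta_y_s", self.n_s)
        take("eta_b_s", self.n_s)
        take("eta_x_se", self.n)
        take("eta_y_se", self.n)
        take("tau", 8)   # log scales: x_e, x_s, x_se, y_e, y_s, y_se, b_e, b_s
        return idx, k


_SCALE_NAMES = ("x_e", "x_s", "x_se", "y_e", "y_s", "y_se", "b_e", "b_s")


class EIVModel:
    """Errors-in-variables mixed-effects regression bound to observations.

    ``observations`` needs columns x_obs, y_obs, sx_obs, sy_obs,
    electrode_id, session_id.  At least two electrodes and two sessions are
    required to identify the crossed random effects.
    """

    def __init__(self, observations: pd.DataFrame,
                 include_random_effects: bool = True):
        req = ["x_obs", "y_obs", "sx_obs", "sy_obs", "electrode_id",
               "session_id"]
        missing = [c for c in req if c not in observations.columns]
        if missing:
            raise ValueError(f"observations missing columns {missing}")
        df = observations.reset_index(drop=True)
        if np.any(df["sx_obs"] <= 0) or np.any(df["sy_obs"] <= 0):
            raise ValueError("measurement SDs must be positive")
        self.df = df
        self.x = df["x_obs"].to_numpy(float)
        self.y = df["y_obs"].to_numpy(float)
        self.sx2 = df["sx_obs"].to_numpy(float) ** 2
        self.sy2 = df["sy_obs"].to_numpy(float) ** 2
        self.e_idx, self.electrodes = pd.factorize(df["electrode_id"])
        self.s_idx, self.sessions = pd.factorize(df["session_id"])
        self.include_random_effects = include_random_effects
        if include_random_effects and (len(self.electrodes) < 2
                                       or len(self.sessions) < 2):
            raise ValueError("need >= 2 electrodes and >= 2 sessions to "
                             "identify crossed random effects")
        self.layout = _Layout(len(df), len(self.electrodes),
                              len(self.sessions))
        self._idx, self.dim = self.layout.slices()

        sd_x = float(np.std(self.x, ddof=1))
        sd_y = float(np.std(self.y, ddof=1))
        ratio = sd_y / sd_x
        # Half-Cauchy widths per scale: 5x the data SD on the matching axis;
        # slope scales use the y/x SD ratio.
        self.hc_width = np.array([5 * sd_x, 5 * sd_x, 5 * sd_x,
                                  5 * sd_y, 5 * sd_y, 5 * sd_y,
                                  ratio, ratio])
        # Weakly informative location/slope priors centered on the data.
        self._x0_prior = (float(self.x.mean()), (5 * sd_x) ** 2)
        self._y0_prior = (float(self.y.mean()), (5 * sd_y) ** 2)
        self._beta_prior_var = (5 * ratio) ** 2

    # -- log posterior and gradient ------------------------------------------

    def _logp_and_grad(self, theta: np.ndarray):
        with np.errstate(over="ignore", invalid="ignore"):
            return self._logp_and_grad_impl(theta)

    def _logp_and_grad_impl(self, theta: np.ndarray):
        ix = self._idx
        n, n_e, n_s = self.layout.n, self.layout.n_e, self.layout.n_s
        beta = theta[ix["beta"]][0]
        x0 = theta[ix["x0"]][0]
        y0 = theta[ix["y0"]][0]
        ex_e = theta[ix["eta_x_e"]]
        ey_e = theta[ix["eta_y_e"]]
        eb_e = theta[ix["eta_b_e"]]
        ex_s = theta[ix["eta_x_s"]]
        ey_s = theta[ix["eta_y_s"]]
        eb_s = theta[ix["eta_b_s"]]
        ex_se = theta[ix["eta_x_se"]]
        ey_se = theta[ix["eta_y_se"]]
        tau = np.clip(theta[ix["tau"]], -40.0, 40.0)  # leapfrog excursions
        sig = np.exp(tau)
        # scale order: x_e, x_s, x_se, y_e, y_s, y_se, b_e, b_s
        free = np.ones(8, dtype=bool)
        if not self.include_random_effects:
            free[[0, 1, 3, 4, 6, 7]] = False   # pin all group scales
            sig = np.where(free, sig, 1e-8)
        s_xe, s_xs, s_xse, s_ye, s_ys, s_yse, s_be, s_bs = sig

        ei, si = self.e_idx, self.s_idx
        xhat = x0 + s_xe * ex_e[ei] + s_xs * ex_s[si] + s_xse * ex_se
        bhat = beta + s_be * eb_e[ei] + s_bs * eb_s[si]
        dev = xhat - x0
        yhat = (y0 + s_ye * ey_e[ei] + s_ys * ey_s[si] + s_yse * ey_se
                + bhat * dev)

        gx = (self.x - xhat) / self.sx2
        gy = (self.y - yhat) / self.sy2
        ll = -0.5 * np.sum((self.x - xhat) ** 2 / self.sx2) \
             - 0.5 * np.sum((self.y - yhat) ** 2 / self.sy2)

        etas = np.concatenate([ex_e, ey_e, eb_e, ex_s, ey_s, eb_s,
                               ex_se, ey_se])
        lp = ll - 0.5 * np.sum(etas ** 2)
        w = self.hc_width
        # half-Cauchy + log-Jacobian for free scales; pinned scales keep a
        # standard-normal prior on tau so those coordinates stay proper.
        hc = (np.log(2.0 / np.pi) + np.log(w) - np.log(w ** 2 + sig ** 2)
              + tau)
        lp += np.sum(np.where(free, hc, -0.5 * tau ** 2))
        m0, v0 = self._x0_prior
        lp += -0.5 * (x0 - m0) ** 2 / v0
        m1, v1 = self._y0_prior
        lp += -0.5 * (y0 - m1) ** 2 / v1
        lp += -0.5 * beta ** 2 / self._beta_prior_var

        # gradients
        g = np.zeros_like(theta)
        dxhat = gx + gy * bhat                    # dlogp / d xhat_i
        g[ix["beta"]] = np.sum(gy * dev) - beta / self._beta_prior_var
        g[ix["x0"]] = np.sum(gx) - (x0 - m0) / v0
        g[ix["y0"]] = np.sum(gy) - (y0 - m1) / v1

        g[ix["eta_x_e"]] = s_xe * np.bincount(ei, dxhat, n_e) - ex_e
        g[ix["eta_y_e"]] = s_ye * np.bincount(ei, gy, n_e) - ey_e
        g[ix["eta_b_e"]] = s_be * np.bincount(ei, gy * dev, n_e) - eb_e
        g[ix["eta_x_s"]] = s_xs * np.bincount(si, dxhat, n_s) - ex_s
        g[ix["eta_y_s"]] = s_ys * np.bincount(si, gy, n_s) - ey_s
        g[ix["eta_b_s"]] = s_bs * np.bincount(si, gy * dev, n_s) - eb_s
        g[ix["eta_x_se"]] = s_xse * dxhat - ex_se
        g[ix["eta_y_se"]] = s_yse * gy - ey_se

        dsig = np.array([
            np.sum(dxhat * ex_e[ei]),
            np.sum(dxhat * ex_s[si]),
            np.sum(dxhat * ex_se),
            np.sum(gy * ey_e[ei]),
            np.sum(gy * ey_s[si]),
            np.sum(gy * ey_se),
            np.sum(gy * dev * eb_e[ei]),
            np.sum(gy * dev * eb_s[si]),
        ])
        # d/dtau of half-Cauchy log density (in sigma) + Jacobian term
        g_tau = dsig * sig - 2.0 * sig ** 2 / (w ** 2 + sig ** 2) + 1.0
        g[ix["tau"]] = np.where(free, g_tau, -tau)
        return lp, g

    def _initial_point(self) -> np.ndarray:
        theta = np.zeros(self.dim)
        ix = self._idx
        xc = self.x - self.x.mean()
        theta[ix["beta"]] = float(xc @ (self.y - self.y.mean()) / (xc @ xc))
        theta[ix["x0"]] = self.x.mean()
        theta[ix["y0"]] = self.y.mean()
        theta[ix["tau"]] = np.log(0.1 * self.hc_width)
        return theta

    def fit(self, n_samples: int = 1000, n_warmup: int = 800,
            seed: int = 0) -> "EIVResults":
        res = sample_hmc(self._logp_and_grad, self._initial_point(),
                         n_samples=n_samples, n_warmup=n_warmup, seed=seed,
                         target_accept=0.85)
        if res.n_divergent > 0.05 * n_samples:
            raise RuntimeError(
                f"HMC diverged on {res.n_divergent}/{n_samples} draws; "
                f"accept rate {res.accept_rate:.2f}")
        return EIVResults(self, res)


class EIVResults:
    """Posterior samples of the EIV mixed-effects regression."""

    def __init__(self, model: EIVModel, hmc):
        self.model = model
        self._hmc = hmc
        ix = model._idx
        th = hmc.samples
        self.beta = th[:, ix["beta"]].ravel()
        self.x0 = th[:, ix["x0"]].ravel()
        self.y0 = th[:, ix["y0"]].ravel()
        scales = np.exp(th[:, ix["tau"]])
        if not model.include_random_effects:
            scales[:, [0, 1, 3, 4, 6, 7]] = 1e-8
        self.scales = pd.DataFrame(scales, columns=list(_SCALE_NAMES))
        s_be = self.scales["b_e"].to_numpy()
        s_bs = self.scales["b_s"].to_numpy()
        self._db_e = th[:, ix["eta_b_e"]] * s_be[:, None]
        self._db_s = th[:, ix["eta_b_s"]] * s_bs[:, None]
        # effective slope: fixed effect plus the average random effects
        self.beta_eff = (self.beta + self._db_s.mean(axis=1)
                         + self._db_e.mean(axis=1))
        # latent coordinates per sample (needed for marginal R^2)
        ei, si = model.e_idx, model.s_idx
        self._xhat = (self.x0[:, None]
                      + self.scales["x_e"].to_numpy()[:, None]
                      * th[:, ix["eta_x_e"]][:, ei]
                      + self.scales["x_s"].to_numpy()[:, None]
                      * th[:, ix["eta_x_s"]][:, si]
                      + self.scales["x_se"].to_numpy()[:, None]
                      * th[:, ix["eta_x_se"]])
        self.n_divergent = hmc.n_divergent
        self.accept_rate = hmc.accept_rate

    def summary(self) -> pd.DataFrame:
        rows = {"beta_eff": self.beta_eff, "beta": self.beta,
                "x0": self.x0, "y0": self.y0}
        rows.update({f"sigma_{k}": self.scales[k].to_numpy()
                     for k in _SCALE_NAMES})
        out = []
        for name, v in rows.items():
            lo, hi = np.percentile(v, [16, 84])
            out.append({"param": name, "mean": v.mean(), "sd": v.std(),
                        "ci68_lo": lo, "ci68_hi": hi})
        return pd.DataFrame(out).set_index("param")

    def plot_fit(self, ax=None):
        """Data with the posterior-mean line and 68% credible band."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.errorbar(m.x, m.y, xerr=np.sqrt(m.sx2), yerr=np.sqrt(m.sy2),
                    fmt="o", ms=3, alpha=0.5)
        xs = np.linspace(m.x.min(), m.x.max(), 50)
        lines = (self.y0[:, None]
                 + self.beta_eff[:, None] * (xs[None, :] - self.x0[:, None]))
        lo, hi = np.percentile(lines, [16, 84], axis=0)
        ax.fill_between(xs, lo, hi, alpha=0.3)
        ax.plot(xs, lines.mean(axis=0))
        return ax


def probability_of_direction(results: EIVResults,
                             sided: str = "one") -> float:
    """Probability of direction of the effective slope.

    One-sided: the fraction of β_eff samples below zero.  Two-sided: the
    smaller of the two tail fractions.  Values are numerically comparable to
    p values (small = strong evidence for the favored direction).
    """
    b = results.beta_eff
    if sided == "one":
        return float(np.mean(b < 0))
    if sided == "two":
        return float(min(np.mean(b < 0), np.mean(b > 0)))
    raise ValueError("sided must be 'one' or 'two'")


def marginal_r2(results: EIVResults) -> float:
    """Marginal R²: fixed-effect variance over fixed + random + noise.

    Per posterior sample, σ²_fixed = var[β_eff·(x̂ − x0)];
    σ²_random = σ²_y,e + σ²_y,s + mean((x̂−x0)²)·(σ²_β,s + σ²_β,e);
    σ²_noise = σ²_y,se + mean(σ²_y,obs).  The posterior median of
    σ²_fixed/(σ²_fixed+σ²_random+σ²_noise) is reported.
    """
    dev = results._xhat - results.x0[:, None]
    fixed = np.var(results.beta_eff[:, None] * dev, axis=1, ddof=1)
    sc = results.scales
    random = (sc["y_e"].to_numpy() ** 2 + sc["y_s"].to_numpy() ** 2
              + np.mean(dev ** 2, axis=1)
              * (sc["b_s"].to_numpy() ** 2 + sc["b_e"].to_numpy() ** 2))
    noise = sc["y_se"].to_numpy() ** 2 + float(np.mean(results.model.sy2))
    r2 = fixed / (fixed + random + noise)
    return float(np.median(r2))
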