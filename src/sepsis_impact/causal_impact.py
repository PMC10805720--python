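"""Bayesian structural time-series causal-impact estimation.

The observed monthly outcome is modeled as

    y_t = mu_t + x_t' beta + eps_t,        eps_t   ~ N(0, sigma_obs^2)
    mu_{t+1} = mu_t + delta_t + eta_mu,    eta_mu  ~ N(0, sigma_level^2)
    delta_{t+1} = delta_t + eta_delta,     eta_delta ~ N(0, sigma_slope^2)

i.e. a local linear trend plus a static regression on contemporaneous
covariates whose coefficients carry a spike-and-slab prior.  The model is
fit to the pre-intervention series by a Gibbs sampler alternating
(a) forward-filtering backward-sampling of the state path, (b) conjugate
inverse-gamma updates of the state innovation variances, and (c) a
collapsed single-site update of the inclusion indicators followed by a
conjugate draw of the observation variance and the included coefficients.
The counterfactual post-intervention trajectory is simulated per retained
draw; the difference to the observed series is the causal effect.

Outcome and covariates are standardized on pre-period statistics only and
back-transformed on output.  Rates are modeled on the raw scale with
Gaussian noise (a documented limitation of this model family).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class BstsConfig:
    """Sampler and prior settings.

    ``n_iterations`` counts retained posterior draws (1000 by default) on
    top of ``n_burnin`` warm-up sweeps.  Prior scales are fractions of the
    pre-period outcome SD; ``expected_model_size`` sets the spike prior
    inclusion probability; ``regression_prior_information_weight`` is the
    effective number of prior observations behind the Zellner-style slab.
    Setting both state SD scales to zero pins the trend at zero, reducing
    the model to pure Bayesian regression (used for closed-form checks).
    """

    n_iterations: int = 1000
    n_burnin: int = 100
    prior_level_sd_scale: float = 0.01
    prior_slope_sd_scale: float = 0.01
    state_prior_sample_size: float = 32.0
    expected_model_size: float = 1.0
    regression_prior_information_weight: float = 0.01
    obs_prior_df: float = 0.01
    obs_prior_expected_r2: float = 0.5
    seed: int = 0
    ci_level: float = 0.95

    def validate(self) -> None:
        if self.n_iterations <= 0 or self.n_burnin < 0:
            raise ValueError("iteration counts must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0,1)")
        if self.prior_level_sd_scale < 0 or self.prior_slope_sd_scale < 0:
            raise ValueError("prior SD scales must be non-negative")


@dataclass
class BstsPosterior:
    """Retained Gibbs draws plus the standardization needed for prediction."""

    level: np.ndarray        # (R, T) state level paths (standardized scale)
    slope: np.ndarray        # (R, T)
    beta: np.ndarray         # (R, K)
    gamma: np.ndarray        # (R, K) 0/1 inclusion indicators
    sigma_obs: np.ndarray    # (R,)
    sigma_level: np.ndarray  # (R,)
    sigma_slope: np.ndarray  # (R,)
    y_mean: float
    y_sd: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    covariate_names: list[str]
    trend_pinned: bool
    config: BstsConfig


@dataclass
class ImpactSummary:
    observed_post_mean: float
    counterfactual_mean: float
    counterfactual_ci: tuple[float, float]
    absolute_effect: float
    absolute_effect_ci: tuple[float, float]
    relative_effect: float
    relative_effect_ci: tuple[float, float]
    cumulative_effect: float
    cumulative_effect_ci: tuple[float, float]
    tail_probability: float

    def to_dict(self) -> dict:
        return {
            "observed_post_mean": self.observed_post_mean,
            "counterfactual_mean": self.counterfactual_mean,
            "counterfactual_ci": list(self.counterfactual_ci),
            "absolute_effect": self.absolute_effect,
            "absolute_effect_ci": list(self.absolute_effect_ci),
            "relative_effect": self.relative_effect,
            "relative_effect_ci": list(self.relative_effect_ci),
            "cumulative_effect": self.cumulative_effect,
            "cumulative_effect_ci": list(self.cumulative_effect_ci),
            "tail_probability": self.tail_probability,
        }


# ---------------------------------------------------------------------------
# Forward filtering, backward sampling for the local linear trend
# ---------------------------------------------------------------------------

def _ffbs(
    z: np.ndarray,
    sigma_obs2: float,
    q_level: float,
    q_slope: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the (level, slope) path given the de-regressed series *z*.

    Explicit 2x2 algebra; the initial state is diffuse around (z_1, 0).
    """
    T = len(z)
    jit = 1e-12
    # filtered moments
    m1 = np.empty(T)
    m2 = np.empty(T)
    p11 = np.empty(T)
    p12 = np.empty(T)
    p22 = np.empty(T)
    # one-step-ahead (predicted) moments at t (from t-1)
    a1 = np.empty(T)
    a2 = np.empty(T)
    r11 = np.empty(T)
    r12 = np.empty(T)
    r22 = np.empty(T)

    # t = 0: prior N((z_0, 0), diag(1, 1)) on the standardized scale
    a1[0], a2[0] = z[0], 0.0
    r11[0], r12[0], r22[0] = 1.0, 0.0, 1.0
    for t in range(T):
        if t > 0:
            a1[t] = m1[t - 1] + m2[t - 1]
            a2[t] = m2[t - 1]
            r11[t] = p11[t - 1] + 2.0 * p12[t - 1] + p22[t - 1] + q_level
            r12[t] = p12[t - 1] + p22[t - 1]
            r22[t] = p22[t - 1] + q_slope
        S = r11[t] + sigma_obs2 + jit
        k1 = r11[t] / S
        k2 = r12[t] / S
        innov = z[t] - a1[t]
        m1[t] = a1[t] + k1 * innov
        m2[t] = a2[t] + k2 * innov
        p11[t] = r11[t] - k1 * r11[t]
        p12[t] = r12[t] - k1 * r12[t]
        p22[t] = r22[t] - k2 * r12[t]

    # backward sampling
    alpha = np.empty((T, 2))
    alpha[T - 1] = _rmvn2(m1[T - 1], m2[T - 1], p11[T - 1], p12[T - 1], p22[T - 1], rng)
    for t in range(T - 2, -1, -1):
        # J = P_t F' (R_{t+1})^{-1}
        b11 = p11[t] + p12[t]  # (P F')_11
        b12 = p12[t]           # (P F')_12
        b21 = p12[t] + p22[t]  # (P F')_21
        b22 = p22[t]           # (P F')_22
        det = r11[t + 1] * r22[t + 1] - r12[t + 1] ** 2
        det = det if abs(det) > jit else jit
        i11, i12, i22 = r22[t + 1] / det, -r12[t + 1] / det, r11[t + 1] / det
        j11 = b11 * i11 + b12 * i12
        j12 = b11 * i12 + b12 * i22
        j21 = b21 * i11 + b22 * i12
        j22 = b21 * i12 + b22 * i22
        d1 = alpha[t + 1, 0] - a1[t + 1]
        d2 = alpha[t + 1, 1] - a2[t + 1]
        mu1 = m1[t] + j11 * d1 + j12 * d2
        mu2 = m2[t] + j21 * d1 + j22 * d2
        # V = P_t - J R_{t+1} J'
        jr11 = j11 * r11[t + 1] + j12 * r12[t + 1]
        jr12 = j11 * r12[t + 1] + j12 * r22[t + 1]
        jr21 = j21 * r11[t + 1] + j22 * r12[t + 1]
        jr22 = j21 * r12[t + 1] + j22 * r22[t + 1]
        v11 = p11[t] - (jr11 * j11 + jr12 * j12)
        v12 = p12[t] - (jr11 * j21 + jr12 * j22)
        v22 = p22[t] - (jr21 * j21 + jr22 * j22)
        alpha[t] = _rmvn2(mu1, mu2, v11, v12, v22, rng)
    return alpha


def _rmvn2(mu1, mu2, v11, v12, v22, rng) -> np.ndarray:
    """One draw from a bivariate normal via a manual Cholesky (degenerate-safe)."""
    v11 = max(v11, 0.0)
    l11 = math.sqrt(v11)
    if l11 > 1e-15:
        l21 = v12 / l11
        rem = v22 - l21 * l21
    else:
        l21 = 0.0
        rem = v22
    l22 = math.sqrt(max(rem, 0.0))
    e1, e2 = rng.standard_normal(2)
    return np.array([mu1 + l11 * e1, mu2 + l21 * e1 + l22 * e2])


def _draw_ig(shape: float, rate: float, rng: np.random.Generator) -> float:
    """Inverse-gamma draw (shape/rate parameterization)."""
    return rate / rng.gamma(shape, 1.0)


# ---------------------------------------------------------------------------
# Spike-and-slab regression block
# ---------------------------------------------------------------------------

class _SpikeSlab:
    """Collapsed single-site Gibbs update of (gamma, sigma_obs^2, beta)."""

    def __init__(self, X: np.ndarray, config: BstsConfig):
        self.X = X
        self.n, self.K = X.shape
        xtx = X.T @ X
        g = config.regression_prior_information_weight
        # average of full and diagonal X'X guards against collinear slabs
        self.omega = (g / max(self.n, 1)) * (0.5 * xtx + 0.5 * np.diag(np.diag(xtx)))
        self.xtx = xtx
        self.pi = min(0.999, max(1e-6, config.expected_model_size / max(self.K, 1)))
        self.nu = config.obs_prior_df
        self.s2 = max(1e-12, 1.0 - config.obs_prior_expected_r2)  # standardized y: var ~ 1

    def _log_marginal(self, gamma: np.ndarray, z: np.ndarray, ztz: float) -> float:
        idx = np.flatnonzero(gamma)
        k = len(idx)
        logprior = k * math.log(self.pi) + (self.K - k) * math.log(1.0 - self.pi)
        if k == 0:
            ss = self.nu * self.s2 + ztz
            return logprior - 0.5 * (self.n + self.nu) * math.log(max(ss, 1e-300))
        omega = self.omega[np.ix_(idx, idx)]
        V = omega + self.xtx[np.ix_(idx, idx)]
        xz = self.X[:, idx].T @ z
        cv = np.linalg.cholesky(V + 1e-12 * np.eye(k))
        co = np.linalg.cholesky(omega + 1e-12 * np.eye(k))
        w = np.linalg.solve(cv, xz)
        ss = self.nu * self.s2 + ztz - float(w @ w)
        logdet_o = 2.0 * np.log(np.diag(co)).sum()
        logdet_v = 2.0 * np.log(np.diag(cv)).sum()
        return (
            logprior
            + 0.5 * (logdet_o - logdet_v)
            - 0.5 * (self.n + self.nu) * math.log(max(ss, 1e-300))
        )

    def update(
        self, z: np.ndarray, gamma: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, float, np.ndarray]:
        """One sweep: gamma (single-site), then sigma_obs^2 and beta conjugately."""
        ztz = float(z @ z)
        gamma = gamma.copy()
        if self.K:
            current = self._log_marginal(gamma, z, ztz)
            for j in rng.permutation(self.K):
                flipped = gamma.copy()
                flipped[j] = 1 - flipped[j]
                other = self._log_marginal(flipped, z, ztz)
                # Gibbs on the two-point conditional
                p_flip = 1.0 / (1.0 + math.exp(min(700.0, current - other)))
                if rng.random() < p_flip:
                    gamma = flipped
                    current = other
        idx = np.flatnonzero(gamma)
        beta = np.zeros(self.K)
        if len(idx) == 0:
            ss = self.nu * self.s2 + ztz
            sigma2 = _draw_ig(0.5 * (self.n + self.nu), 0.5 * ss, rng)
            return gamma, sigma2, beta
        k = len(idx)
        V = self.omega[np.ix_(idx, idx)] + self.xtx[np.ix_(idx, idx)]
        cv = np.linalg.cholesky(V + 1e-12 * np.eye(k))
        xz = self.X[:, idx].T @ z
        w = np.linalg.solve(cv, xz)
        bhat = np.linalg.solve(cv.T, w)
        ss = self.nu * self.s2 + ztz - float(w @ w)
        sigma2 = _draw_ig(0.5 * (self.n + self.nu), 0.5 * max(ss, 1e-12), rng)
        eps = rng.standard_normal(k)
        beta[idx] = bhat + math.sqrt(sigma2) * np.linalg.solve(cv.T, eps)
        return gamma, sigma2, beta


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit(
    y_pre: Sequence[float],
    X_pre: Optional[np.ndarray],
    config: BstsConfig,
    covariate_names: Optional[list[str]] = None,
) -> BstsPosterior:
    """Fit the structural model to the pre-intervention series.

    *X_pre* may be ``None`` or a (T, K) matrix; columns are standardized
    internally on pre-period statistics (zero-variance columns are left
    centered only).
    """
    config.validate()
    y = np.asarray(y_pre, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite outcome values in the pre-period series")
    T = len(y)
    if T < 4:
        raise ValueError("need at least 4 pre-intervention points (state dimension + 2)")

    if X_pre is None:
        X_pre = np.empty((T, 0))
    X = np.asarray(X_pre, dtype=float)
    if X.shape[0] != T:
        raise ValueError("covariate matrix and outcome length differ")
    K = X.shape[1]
    if covariate_names is None:
        covariate_names = [f"x{j}" for j in range(K)]

    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=0))
    if y_sd <= 0:
        y_sd = 1.0
    ys = (y - y_mean) / y_sd
    x_mean = X.mean(axis=0) if K else np.empty(0)
    x_sd = X.std(axis=0, ddof=0) if K else np.empty(0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Xs = (X - x_mean) / x_sd if K else X

    rng = np.random.default_rng(np.random.SeedSequence([max(0, config.seed), 11]))
    trend_pinned = config.prior_level_sd_scale == 0.0 and config.prior_slope_sd_scale == 0.0

    # state-variance priors (standardized scale)
    nu_s = config.state_prior_sample_size
    s_level2 = config.prior_level_sd_scale ** 2
    s_slope2 = config.prior_slope_sd_scale ** 2

    ss = _SpikeSlab(Xs, config)

    n_total = config.n_iterations + config.n_burnin
    R = config.n_iterations
    out_level = np.zeros((R, T))
    out_slope = np.zeros((R, T))
    out_beta = np.zeros((R, K))
    out_gamma = np.zeros((R, K), dtype=int)
    out_sobs = np.zeros(R)
    out_slev = np.zeros(R)
    out_sslp = np.zeros(R)

    # initial values
    beta = np.zeros(K)
    gamma = np.zeros(K, dtype=int)
    sigma_obs2 = 1.0
    q_level = s_level2 if not trend_pinned else 0.0
    q_slope = s_slope2 if not trend_pinned else 0.0
    level = np.zeros(T)
    slope = np.zeros(T)

    for it in range(n_total):
        resid = ys - (Xs @ beta if K else 0.0)
        if trend_pinned:
            level[:] = 0.0
            slope[:] = 0.0
        else:
            alpha = _ffbs(resid, sigma_obs2, q_level, q_slope, rng)
            level, slope = alpha[:, 0], alpha[:, 1]
            # conjugate inverse-gamma updates of the innovation variances
            eta_l = level[1:] - level[:-1] - slope[:-1]
            eta_s = slope[1:] - slope[:-1]
            q_level = _draw_ig(
                0.5 * (nu_s + T - 1), 0.5 * (nu_s * s_level2 + float(eta_l @ eta_l)), rng
            )
            q_slope = _draw_ig(
                0.5 * (nu_s + T - 1), 0.5 * (nu_s * s_slope2 + float(eta_s @ eta_s)), rng
            )

        z = ys - level
        if K:
            gamma, sigma_obs2, beta = ss.update(z, gamma, rng)
        else:
            ztz = float(z @ z)
            sigma_obs2 = _draw_ig(0.5 * (T + ss.nu), 0.5 * (ss.nu * ss.s2 + ztz), rng)

        if it >= config.n_burnin:
            r = it - config.n_burnin
            out_level[r] = level
            out_slope[r] = slope
            out_beta[r] = beta
            out_gamma[r] = gamma
            out_sobs[r] = math.sqrt(sigma_obs2)
            out_slev[r] = math.sqrt(q_level)
            out_sslp[r] = math.sqrt(q_slope)

    return BstsPosterior(
        level=out_level,
        slope=out_slope,
        beta=out_beta,
        gamma=out_gamma,
        sigma_obs=out_sobs,
        sigma_level=out_slev,
        sigma_slope=out_sslp,
        y_mean=y_mean,
        y_sd=y_sd,
        x_mean=x_mean,
        x_sd=x_sd,
        covariate_names=covariate_names,
        trend_pinned=trend_pinned,
        config=config,
    )


def predict_counterfactual(
    posterior: BstsPosterior, X_post: Optional[np.ndarray], seed: Optional[int] = None
) -> np.ndarray:
    """Counterfactual draw matrix (retained draws x post months), original units.

    Each retained draw's trend is iterated forward with that draw's sampled
    innovation SDs; the regression term and observation noise are added.
    """
    R, T = posterior.level.shape
    K = posterior.beta.shape[1]
    if isinstance(X_post, (int, np.integer)):  # covariate-free model: integer horizon
        if K:
            raise ValueError("model has covariates; pass the post-period covariate matrix")
        X_post = np.zeros((int(X_post), 0))
    if X_post is None:
        raise ValueError("post-period covariates (or an integer horizon) required")
    X_post = np.asarray(X_post, dtype=float)
    if X_post.ndim != 2 or X_post.shape[1] != K:
        raise ValueError(
            f"covariate column mismatch: model has {K} columns, "
            f"prediction input has shape {X_post.shape}"
        )
    H = X_post.shape[0]
    if H == 0:
        raise ValueError("prediction horizon must be positive")
    Xs = (X_post - posterior.x_mean) / posterior.x_sd if K else np.zeros((H, 0))

    rng = np.random.default_rng(
        np.random.SeedSequence([max(0, posterior.config.seed if seed is None else seed), 13])
    )
    draws = np.empty((R, H))
    reg = Xs @ posterior.beta.T if K else np.zeros((H, R))  # (H, R)
    mu = posterior.level[:, -1].copy()
    delta = posterior.slope[:, -1].copy()
    sl = posterior.sigma_level
    sp = posterior.sigma_slope
    so = posterior.sigma_obs
    if posterior.trend_pinned:
        mu = np.zeros(R)
        delta = np.zeros(R)
    for h in range(H):
        mu = mu + delta + sl * rng.standard_normal(R)
        delta = delta + sp * rng.standard_normal(R)
        draws[:, h] = mu + reg[h] + so * rng.standard_normal(R)
    return posterior.y_mean + posterior.y_sd * draws


def summarize_effect(
    counterfactual_draws: np.ndarray,
    observed_post: Sequence[float],
    ci_level: float = 0.95,
) -> ImpactSummary:
    """Posterior effect summaries from the counterfactual draw matrix.

    The one-sided tail-area probability is the posterior mass of cumulative
    effects opposite in sign to the median effect (ties split evenly), the
    Bayesian analog of a one-sided p value.
    """
    draws = np.asarray(counterfactual_draws, dtype=float)
    obs = np.asarray(observed_post, dtype=float)
    if draws.ndim != 2 or draws.shape[0] == 0:
        raise ValueError("empty counterfactual draw matrix")
    if draws.shape[1] != len(obs):
        raise ValueError("draw matrix and observed series aligned by month required")
    R, H = draws.shape
    alpha = (1.0 - ci_level) / 2.0
    qs = (100 * alpha, 100 * (1 - alpha))

    cf_mean_draws = draws.mean(axis=1)
    obs_mean = float(obs.mean())
    abs_draws = obs_mean - cf_mean_draws
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_draws = abs_draws / cf_mean_draws
    cum_draws = H * abs_draws  # sum of pointwise effects == H * mean effect

    med = float(np.median(cum_draws))
    sign = 1.0 if med >= 0 else -1.0
    opposite = float(np.sum(sign * cum_draws < 0))
    ties = float(np.sum(cum_draws == 0))
    tail = (opposite + 0.5 * ties + 0.5) / (R + 1)

    def _ci(a):
        lo, hi = np.percentile(a, qs)
        return (float(lo), float(hi))

    return ImpactSummary(
        observed_post_mean=obs_mean,
        counterfactual_mean=float(cf_mean_draws.mean()),
        counterfactual_ci=_ci(cf_mean_draws),
        absolute_effect=float(abs_draws.mean()),
        absolute_effect_ci=_ci(abs_draws),
        relative_effect=float(np.nanmean(rel_draws)),
        relative_effect_ci=_ci(rel_draws[np.isfinite(rel_draws)]),
        cumulative_effect=float(cum_draws.mean()),
        cumulative_effect_ci=_ci(cum_draws),
        tail_probability=float(tail),
    )


def survivors_averted(absolute_effect_rate: float, n_post: int) -> int:
    """Convert an absolute mortality-rate reduction into additional survivors."""
    return int(round(-absolute_effect_rate * n_post))


# ---------------------------------------------------------------------------
# Convenience: series-level interface and plotting
# ---------------------------------------------------------------------------

def estimate_impact(
    series,
    config: BstsConfig,
    covariate_cols: Optional[list[str]] = None,
) -> tuple[BstsPosterior, np.ndarray, ImpactSummary]:
    """Fit on the pre period of a monthly-series table and summarize the post period.

    *series* is the ``monthly_series.csv`` shape: columns ``y``, ``period``
    and covariates.
    """
    import pandas as pd  # local import keeps numpy-only callers light

    df = pd.DataFrame(series)
    if covariate_cols is None:
        reserved = {"month", "y", "period", "n"}
        covariate_cols = [c for c in df.columns if c not in reserved]
    pre = df[df["period"] == "pre"]
    post = df[df["period"] == "post"]
    if post.empty:
        raise ValueError("no post-period months in series")
    posterior = fit(
        pre["y"].to_numpy(),
        pre[covariate_cols].to_numpy(float),
        config,
        covariate_names=list(covariate_cols),
    )
    draws = predict_counterfactual(posterior, post[covariate_cols].to_numpy(float))
    summary = summarize_effect(draws, post["y"].to_numpy(), ci_level=config.ci_level)
    return posterior, draws, summary


def render_impact_panels(
    series,
    posterior: BstsPosterior,
    counterfactual_draws: np.ndarray,
    out_path,
    ci_level: float = 0.95,
) -> None:
    """Three stacked panels: original, pointwise effect, cumulative effect."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    df = pd.DataFrame(series)
    pre = df[df["period"] == "pre"]
    post = df[df["period"] == "post"]
    a = (1 - ci_level) / 2
    t_pre = np.arange(len(pre))
    t_post = np.arange(len(pre), len(pre) + len(post))

    reg = 0.0
    if posterior.beta.shape[1]:
        Xs = (pre[posterior.covariate_names].to_numpy(float) - posterior.x_mean) / posterior.x_sd
        reg = (Xs @ posterior.beta.T).T  # (R, T_pre)
    fitted = posterior.y_mean + posterior.y_sd * (posterior.level + reg)
    pre_mean = fitted.mean(axis=0)
    pre_lo, pre_hi = np.percentile(fitted, [100 * a, 100 * (1 - a)], axis=0)
    cf_mean = counterfactual_draws.mean(axis=0)
    cf_lo, cf_hi = np.percentile(counterfactual_draws, [100 * a, 100 * (1 - a)], axis=0)

    point = post["y"].to_numpy()[None, :] - counterfactual_draws
    pt_mean = point.mean(axis=0)
    pt_lo, pt_hi = np.percentile(point, [100 * a, 100 * (1 - a)], axis=0)
    cum = np.cumsum(point, axis=1)
    cum_mean = cum.mean(axis=0)
    cum_lo, cum_hi = np.percentile(cum, [100 * a, 100 * (1 - a)], axis=0)

    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(9, 8))
    go_live_x = len(pre) - 0.5
    axes[0].plot(np.r_[t_pre, t_post], df["y"].to_numpy(), "k.-", label="observed")
    axes[0].plot(t_pre, pre_mean, "b--", label="model")
    axes[0].fill_between(t_pre, pre_lo, pre_hi, color="b", alpha=0.2)
    axes[0].plot(t_post, cf_mean, "b--")
    axes[0].fill_between(t_post, cf_lo, cf_hi, color="b", alpha=0.2)
    axes[0].set_ylabel("original")
    axes[0].legend(loc="best", fontsize=8)
    axes[1].axhline(0, color="gray", lw=0.8)
    axes[1].plot(t_post, pt_mean, "b--")
    axes[1].fill_between(t_post, pt_lo, pt_hi, color="b", alpha=0.2)
    axes[1].set_ylabel("pointwise")
    axes[2].axhline(0, color="gray", lw=0.8)
    axes[2].plot(t_post, cum_mean, "b--")
    axes[2].fill_between(t_post, cum_lo, cum_hi, color="b", alpha=0.2)
    axes[2].set_ylabel("cumulative")
    axes[2].set_xlabel("month index")
    for ax in axes:
        ax.axvline(go_live_x, color="gray", ls="-", lw=1)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
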