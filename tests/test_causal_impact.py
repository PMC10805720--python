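"""Structural time-series model: degenerate cases, conjugate oracle, effect summaries."""

from __future__ import annotations

import numpy as np
import pytest

from sepsis_impact.causal_impact import (
    BstsConfig,
    BstsPosterior,
    _SpikeSlab,
    fit,
    predict_counterfactual,
    summarize_effect,
    survivors_averted,
)


def _make_posterior(level_end, slope_end, R=50, T=10, y_mean=0.0, y_sd=1.0):
    """Hand-built noiseless posterior for exercising the forecaster in isolation."""
    level = np.zeros((R, T))
    level[:, -1] = level_end
    slope = np.full((R, T), slope_end)
    zeros = np.zeros(R)
    return BstsPosterior(
        level=level,
        slope=slope,
        beta=np.zeros((R, 0)),
        gamma=np.zeros((R, 0), dtype=int),
        sigma_obs=zeros,
        sigma_level=zeros,
        sigma_slope=zeros,
        y_mean=y_mean,
        y_sd=y_sd,
        x_mean=np.empty(0),
        x_sd=np.empty(0),
        covariate_names=[],
        trend_pinned=False,
        config=BstsConfig(seed=0),
    )


class TestFit:
    def test_constant_series_counterfactual_recovers_constant(self):
        y = np.full(20, 7.5)
        cfg = BstsConfig(n_iterations=800, n_burnin=100, seed=4)
        post = fit(y, None, cfg)
        draws = predict_counterfactual(post, 5)
        cf = draws.mean(axis=1)
        mcse = cf.std() / np.sqrt(len(cf)) + 1e-12
        assert abs(cf.mean() - 7.5) <= max(2 * mcse, 0.02)
        # slope draws centered at zero
        assert abs(post.slope[:, -1].mean()) <= 3 * post.slope[:, -1].std() / np.sqrt(800) + 1e-3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit(np.ones(3), None, BstsConfig())

    def test_non_finite_outcome_rejected(self):
        y = np.ones(12)
        y[3] = np.nan
        with pytest.raises(ValueError):
            fit(y, None, BstsConfig())

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        X = rng.normal(size=(20, 3))
        a = fit(y, X, BstsConfig(n_iterations=200, n_burnin=20, seed=9))
        b = fit(y, X, BstsConfig(n_iterations=200, n_burnin=20, seed=9))
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.level, b.level)
        np.testing.assert_array_equal(a.sigma_obs, b.sigma_obs)

    def test_conjugate_regression_oracle_with_pinned_trend(self):
        """With state variances pinned to zero the coefficient posterior matches
        the conjugate Bayesian linear regression closed form."""
        rng = np.random.default_rng(1)
        T = 30
        x = rng.normal(size=(T, 1))
        y = 2.0 * x[:, 0] + rng.normal(scale=0.5, size=T)
        cfg = BstsConfig(
            prior_level_sd_scale=0.0,
            prior_slope_sd_scale=0.0,
            n_iterations=2000,
            n_burnin=200,
            expected_model_size=1,
            seed=1,
        )
        post = fit(y, x, cfg)
        assert post.gamma.mean() > 0.99  # strong signal: always included

        ys = (y - y.mean()) / y.std()
        xs = (x - x.mean(0)) / x.std(0)
        slab = _SpikeSlab(xs, cfg)
        V = slab.omega + xs.T @ xs
        bhat = np.linalg.solve(V, xs.T @ ys)
        dfp = T + slab.nu
        ss = slab.nu * slab.s2 + ys @ ys - bhat @ (V @ bhat)
        sd_closed = np.sqrt(ss / (dfp - 2) * np.linalg.inv(V)[0, 0])
        mcse = post.beta[:, 0].std() / np.sqrt(post.beta.shape[0])
        assert abs(post.beta[:, 0].mean() - bhat[0]) <= 3 * mcse
        assert post.beta[:, 0].std() == pytest.approx(sd_closed, rel=0.15)

    def test_parameter_recovery_with_null_covariates(self):
        """beta = (2, 0, 0): the signal coefficient's CI covers 2 and the null
        covariates stay excluded most of the time, in >= 80% of replicates."""
        ok_ci, ok_spike = 0, 0
        n_rep = 10
        for r in range(n_rep):
            rng = np.random.default_rng(50 + r)
            T = 60
            X = rng.normal(size=(T, 3))
            y = 1.0 + 2.0 * X[:, 0] + rng.normal(scale=0.8, size=T)
            post = fit(y, X, BstsConfig(n_iterations=600, n_burnin=100, seed=50 + r))
            b0 = post.beta[:, 0] * post.y_sd / post.x_sd[0]
            lo, hi = np.percentile(b0, [2.5, 97.5])
            ok_ci += lo <= 2.0 <= hi
            ok_spike += (post.gamma[:, 1].mean() < 0.5) and (post.gamma[:, 2].mean() < 0.5)
        assert ok_ci >= 0.8 * n_rep
        assert ok_spike >= 0.8 * n_rep


class TestPredict:
    def test_noiseless_linear_extrapolation_is_exact(self):
        post = _make_posterior(level_end=3.0, slope_end=0.5)
        draws = predict_counterfactual(post, 4)
        for k in range(4):
            np.testing.assert_allclose(draws[:, k], 3.0 + (k + 1) * 0.5, atol=1e-12)

    def test_back_transform_round_trip(self):
        """A series in original units yields predictions on that scale."""
        rng = np.random.default_rng(8)
        y = 250.0 + 40.0 * rng.normal(size=24)
        post = fit(y, None, BstsConfig(n_iterations=400, n_burnin=50, seed=8))
        draws = predict_counterfactual(post, 5)
        assert 150 < draws.mean() < 350

    def test_covariate_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        post = fit(rng.normal(size=15), rng.normal(size=(15, 2)), BstsConfig(n_iterations=100, n_burnin=10, seed=9))
        with pytest.raises(ValueError, match="mismatch"):
            predict_counterfactual(post, rng.normal(size=(5, 3)))

    def test_interval_nesting(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=24)
        post = fit(y, None, BstsConfig(n_iterations=400, n_burnin=50, seed=10))
        draws = predict_counterfactual(post, 6)
        for m in range(6):
            lo50, hi50 = np.percentile(draws[:, m], [25, 75])
            lo95, hi95 = np.percentile(draws[:, m], [2.5, 97.5])
            assert lo95 <= lo50 <= hi50 <= hi95


class TestSummarize:
    def test_mortality_effect_arithmetic(self):
        """Counterfactual 11.39% vs observed 9.49%: -1.90 point absolute,
        -17% relative effect."""
        draws = np.full((400, 5), 11.39)
        obs = np.full(5, 9.49)
        s = summarize_effect(draws, obs)
        assert s.absolute_effect == pytest.approx(-1.90, abs=1e-9)
        assert s.relative_effect == pytest.approx(-0.1668, abs=5e-4)
        assert round(100 * s.relative_effect) == -17

    def test_exact_null_gives_zero_effect_and_half_tail(self):
        draws = np.full((999, 4), 3.5)
        obs = np.full(4, 3.5)
        s = summarize_effect(draws, obs)
        assert s.absolute_effect == 0.0
        assert s.tail_probability == pytest.approx(0.5, abs=1e-9)

    def test_cumulative_equals_sum_of_pointwise_per_draw(self):
        rng = np.random.default_rng(11)
        draws = rng.normal(size=(200, 6))
        obs = rng.normal(size=6)
        s = summarize_effect(draws, obs)
        point = obs[None, :] - draws
        np.testing.assert_allclose(point.sum(axis=1).mean(), s.cumulative_effect, atol=1e-12)
        assert s.cumulative_effect == pytest.approx(6 * s.absolute_effect, abs=1e-12)

    def test_tail_probability_bounds(self):
        rng = np.random.default_rng(12)
        draws = rng.normal(10, 1, size=(300, 3))
        s = summarize_effect(draws, np.full(3, 30.0))  # effect far from zero
        assert 0.0 < s.tail_probability < 1.0
        assert s.tail_probability < 0.01

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_effect(np.empty((0, 3)), np.zeros(3))

    def test_survivor_conversion(self):
        assert survivors_averted(-0.019, 1152) == 22


def test_render_impact_panels_writes_file(tmp_path):
    import pandas as pd

    rng = np.random.default_rng(13)
    y = 0.1 + rng.normal(scale=0.01, size=28)
    X = rng.normal(size=(28, 2))
    series = pd.DataFrame(
        {"month": range(28), "y": y, "c1": X[:, 0], "c2": X[:, 1],
         "period": ["pre"] * 23 + ["post"] * 5, "n": 100}
    )
    post = fit(y[:23], X[:23], BstsConfig(n_iterations=200, n_burnin=20, seed=13))
    post.covariate_names = ["c1", "c2"]
    draws = predict_counterfactual(post, X[23:])
    out = tmp_path / "panels.png"
    from sepsis_impact.causal_impact import render_impact_panels

    render_impact_panels(series, post, draws, out)
    assert out.exists() and out.stat().st_size > 0
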