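"""OLS, effect-table, Tukey HSD and power contracts, each against an
independent oracle (hand normal-equation solve, t^2 = F and q = t*sqrt(2)
identities, Monte-Carlo simulation)."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from taptiming.regression import (
    OLSFit,
    PowerSpec,
    TimingRegression,
    fit_ols,
    posthoc_power,
    trial_phase_means,
    tukey_hsd,
)


class TestFitOLS:
    def test_six_point_toy_matches_hand_normal_equations(self):
        # y = 2 + 3*x1 - 1*x2 + noise, solved by hand via (X'X)^-1 X'y
        X = np.array(
            [
                [1.0, 0.0, 1.0],
                [1.0, 1.0, 0.0],
                [1.0, 2.0, 1.0],
                [1.0, 3.0, 0.0],
                [1.0, 4.0, 1.0],
                [1.0, 5.0, 0.0],
            ]
        )
        y = np.array([1.2, 5.1, 7.0, 10.9, 13.1, 17.2])
        beta_hand = np.linalg.inv(X.T @ X) @ X.T @ y
        fit = fit_ols(y, X, names=["const", "x1", "x2"])
        assert np.allclose(fit.params, beta_hand, atol=1e-12)
        # SEs from the unbiased residual variance, also by hand
        resid = y - X @ beta_hand
        s2 = resid @ resid / (6 - 3)
        se_hand = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert np.allclose(fit.bse, se_hand, atol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = X @ [1.0, 2.0, -0.5] + rng.normal(size=30)
        ours = fit_ols(y, X)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(ours.params, ref.params)
        assert np.allclose(ours.bse, ref.bse)
        assert ours.rsquared == pytest.approx(ref.rsquared)
        assert ours.fvalue == pytest.approx(ref.fvalue)

    def test_exact_linear_data(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        y = 4.0 - 2.0 * np.arange(6.0)
        fit = fit_ols(y, X)
        assert np.allclose(fit.resid, 0.0, atol=1e-10)
        assert fit.rsquared == pytest.approx(1.0)

    def test_intercept_only_gives_mean(self):
        y = np.array([3.0, 5.0, 10.0, 2.0])
        fit = fit_ols(y, np.ones((4, 1)))
        assert fit.params[0] == pytest.approx(y.mean())

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
        y = rng.normal(size=40)
        fit = fit_ols(y, X)
        assert np.allclose(X.T @ fit.resid, 0.0, atol=1e-8)
        # R^2 equals squared correlation of y and fitted values
        r = np.corrcoef(y, fit.fitted)[0, 1]
        assert fit.rsquared == pytest.approx(r**2)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(np.zeros(10), X, names=["const", "a", "b"])


def _toy_obs(n_per_cell=6, delta_phase=40.0, noise=5.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for design in ["blocked", "alternating"]:
        for mode in ["synchronized", "syncopated"]:
            for phase in ["pacing", "continuation"]:
                base = delta_phase if phase == "continuation" else 0.0
                for t in range(n_per_cell):
                    rows.append(
                        {
                            "participant_id": f"{design[0]}{t}",
                            "design": design,
                            "mode": mode,
                            "phase": phase,
                            "trial": t,
                            "asynchrony_ms": base + rng.normal(0, noise),
                        }
                    )
    return pd.DataFrame(rows)


class TestTimingRegression:
    def test_recovers_planted_phase_effect(self):
        df = _toy_obs(delta_phase=48.8, seed=2)
        fit = TimingRegression(df, "asynchrony_ms", interactions=False).fit()
        name = [n for n in fit.params.index if "phase" in n][0]
        assert abs(fit.params[name] - 48.8) < 3 * fit.bse[name]

    def test_effect_table_f_equals_t_squared_single_factor(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "phase": ["pacing"] * 10 + ["continuation"] * 10,
                "asynchrony_ms": np.r_[rng.normal(0, 1, 10), rng.normal(1, 1, 10)],
            }
        )
        fit = TimingRegression(df, "asynchrony_ms", factors=("phase",),
                               interactions=False).fit()
        et = fit.effect_table()
        t = st.ttest_ind(
            df[df.phase == "continuation"]["asynchrony_ms"],
            df[df.phase == "pacing"]["asynchrony_ms"],
        ).statistic
        assert et.loc[0, "F"] == pytest.approx(t**2, rel=1e-10)

    def test_effect_table_scale_invariant(self):
        df = _toy_obs(seed=4)
        et1 = TimingRegression(df, "asynchrony_ms").fit().effect_table()
        df2 = df.assign(asynchrony_ms=df["asynchrony_ms"] * 2)
        et2 = TimingRegression(df2, "asynchrony_ms").fit().effect_table()
        assert np.allclose(et1["F"], et2["F"])
        assert np.allclose(et1["partial_eta2"], et2["partial_eta2"])

    def test_null_factor_type_i_error_near_alpha(self):
        # mode has no true effect; p-values should be ~uniform
        rng = np.random.default_rng(5)
        hits, reps = 0, 200
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "mode": np.repeat(["synchronized", "syncopated"], 15),
                    "asynchrony_ms": rng.normal(size=30),
                }
            )
            et = TimingRegression(df, "asynchrony_ms", factors=("mode",),
                                  interactions=False).fit().effect_table()
            hits += et.loc[0, "p"] < 0.05
        # binomial 3-sigma band around 0.05
        assert 0.05 * reps - 3 * np.sqrt(reps * 0.05 * 0.95) <= hits
        assert hits <= 0.05 * reps + 3 * np.sqrt(reps * 0.05 * 0.95)

    def test_fitted_plus_residuals_reconstruct_outcome(self):
        df = _toy_obs(seed=6)
        fit = TimingRegression(df, "asynchrony_ms").fit()
        assert np.allclose(
            fit.fittedvalues + fit.resid, df["asynchrony_ms"], atol=1e-9
        )

    def test_summary_mentions_formula_and_r2(self):
        fit = TimingRegression(_toy_obs(seed=7), "asynchrony_ms").fit()
        text = fit.summary()
        assert "R^2" in text and "phase" in text


def test_trial_phase_means_collapses_taps():
    df = pd.DataFrame(
        {
            "participant_id": ["P0"] * 4,
            "design": ["blocked"] * 4,
            "mode": ["synchronized"] * 4,
            "phase": ["pacing", "pacing", "continuation", "continuation"],
            "trial": [0, 0, 0, 0],
            "asynchrony_ms": [-10.0, -20.0, 30.0, 50.0],
        }
    )
    out = trial_phase_means(df, "asynchrony_ms")
    assert len(out) == 2
    assert sorted(out["asynchrony_ms"]) == [-15.0, 40.0]


class TestTukeyHSD:
    def test_identical_groups_nothing_significant(self):
        g = {"a": np.arange(5.0), "b": np.arange(5.0), "c": np.arange(5.0)}
        table = tukey_hsd(g)
        assert np.allclose(table["diff"], 0.0)
        assert not table["significant"].any()

    def test_two_group_q_equals_t_times_sqrt2(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        table = tukey_hsd({"a": a, "b": b})
        t = st.ttest_ind(a, b).statistic
        assert table.loc[0, "q"] == pytest.approx(abs(t) * np.sqrt(2), rel=1e-10)
        # decision agrees with the pooled-variance t test
        t_crit = st.t.ppf(0.975, len(a) + len(b) - 2)
        assert table.loc[0, "significant"] == (abs(t) > t_crit)

    def test_three_groups_match_statsmodels(self):
        rng = np.random.default_rng(9)
        groups = {k: rng.normal(mu, 1, 10) for k, mu in
                  [("a", 0.0), ("b", 0.8), ("c", 2.0)]}
        ours = tukey_hsd(groups)
        data = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), 10)
        ref = pairwise_tukeyhsd(data, labels, alpha=0.05)
        assert np.allclose(ours["diff"], ref.meandiffs)
        assert np.allclose(ours["p"], ref.pvalues, atol=1e-6)
        assert list(ours["significant"]) == list(ref.reject)

    def test_critical_q_matches_monte_carlo_null_quantile(self):
        # simulate the null max-studentized-range distribution
        rng = np.random.default_rng(10)
        k, n, reps = 3, 6, 4000
        x = rng.normal(size=(reps, k, n))
        means = x.mean(axis=2)
        msw = x.var(axis=2, ddof=1).mean(axis=1)
        q = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(msw / n)
        mc_crit = np.quantile(q, 0.95)
        exact = st.studentized_range.ppf(0.95, k, k * (n - 1))
        se = (np.quantile(q, 0.96) - np.quantile(q, 0.94)) / 2  # crude MC wiggle
        assert abs(mc_crit - exact) < 3 * max(se, 0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0, 2.0], "b": [1.0]})


class TestPosthocPower:
    def test_zero_effect_gives_alpha(self):
        assert posthoc_power(PowerSpec(0.0, 23, 3, 0.05)) == pytest.approx(0.05)
        assert posthoc_power(PowerSpec(0.0, 23, 3, 0.01)) == pytest.approx(0.01)

    def test_power_increases_with_n_and_f(self):
        powers_n = [posthoc_power(PowerSpec(0.39, n, 3)) for n in (10, 23, 50, 200)]
        assert all(a < b for a, b in zip(powers_n, powers_n[1:]))
        powers_f = [posthoc_power(PowerSpec(f, 23, 3)) for f in (0.14, 0.39, 0.59)]
        assert all(a < b for a, b in zip(powers_f, powers_f[1:]))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            posthoc_power(PowerSpec(0.2, 4, 3))

    @pytest.mark.parametrize("f,n,k", [(0.39, 23, 3), (0.59, 23, 3)])
    def test_matches_monte_carlo_regression_simulation(self, f, n, k):
        # simulate regression F tests at the stated Cohen's f
        rng = np.random.default_rng(11)
        reps = 10_000
        X = rng.normal(size=(n, k))
        X -= X.mean(axis=0)
        Q, _ = np.linalg.qr(X)  # orthonormal predictors
        lam = f**2 * n
        beta = np.zeros(k)
        beta[0] = np.sqrt(lam)  # ||Q beta||^2 = lam
        Xc = np.column_stack([np.ones(n), Q])
        Y = (Q @ beta)[:, None] + rng.normal(size=(n, reps))
        # vectorized OLS F tests of the k predictors
        coef, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
        fitted = Xc @ coef
        rss = ((Y - fitted) ** 2).sum(axis=0)
        tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        fstat = ((tss - rss) / k) / (rss / (n - k - 1))
        crit = st.f.ppf(0.95, k, n - k - 1)
        mc_power = (fstat > crit).mean()
        mc_se = np.sqrt(mc_power * (1 - mc_power) / reps)
        expected = posthoc_power(PowerSpec(f, n, k, 0.05))
        assert abs(mc_power - expected) < 2 * max(mc_se, 1e-3)
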