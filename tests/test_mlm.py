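"""Random-intercept mixed model: degenerate limits, oracle agreement with
statsmodels MixedLM, likelihood-ratio tests and the robust reweighted fit."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from ctradiomics.mlm import fit_mlm, fit_robust_mlm, lrt, marginal_r2, MLMFit

from oracles import ols_fit


def simulate(rng, G=12, m=6, beta=(1.0, 0.5), s_b=0.8, s_e=0.6):
    n = G * m
    groups = np.repeat(np.arange(G), m)
    x = rng.normal(size=n)
    b = rng.normal(0, s_b, G)
    y = beta[0] + beta[1] * x + b[groups] + rng.normal(0, s_e, n)
    X = pd.DataFrame({"intercept": np.ones(n), "x": x})
    return y, X, groups


class TestFitMLM:
    def test_zero_icc_limit_matches_ols(self, rng):
        # no between-patient variance (noise group-centred so the REML
        # estimate sits at its boundary): the fit must collapse to OLS
        G, m = 12, 6
        n = G * m
        groups = np.repeat(np.arange(G), m)
        x = rng.normal(size=n)
        e = rng.normal(0, 0.6, n)
        e -= np.repeat([e[groups == g].mean() for g in range(G)], m)
        y = 1.0 + 0.5 * x + e
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        fit = fit_mlm(y, X, groups)
        beta_ols, se_ols, _ = ols_fit(y, X.values)
        assert np.allclose(fit.params, beta_ols, atol=1e-6)
        assert fit.sigma2_patient < 1e-6

    def test_noise_free_recovery(self, rng):
        y, X, groups = simulate(rng, s_b=0.0, s_e=0.0)
        fit = fit_mlm(y + 0.0, X, groups)
        assert np.allclose(fit.params, [1.0, 0.5], atol=1e-8)
        assert fit.sigma2_resid < 1e-8

    @pytest.mark.parametrize("method", ["REML", "ML"])
    def test_matches_statsmodels_mixedlm(self, rng, method):
        y, X, groups = simulate(rng)
        fit = fit_mlm(y, X, groups, method=method)
        ref = sm.MixedLM(y, X.values, groups).fit(reml=(method == "REML"))
        assert np.allclose(fit.params, ref.fe_params, atol=1e-5)
        assert fit.sigma2_resid == pytest.approx(ref.scale, abs=1e-5)
        assert fit.sigma2_patient == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), abs=1e-4)
        assert fit.loglike == pytest.approx(ref.llf, abs=1e-6)

    def test_one_observation_per_group_collapses_to_ols(self, rng):
        n = 30
        x = rng.normal(size=n)
        y = 2.0 + 0.3 * x + rng.normal(0, 1, n)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        fit = fit_mlm(y, X, np.arange(n))
        beta_ols, _, _ = ols_fit(y, X.values)
        assert np.allclose(fit.params, beta_ols, atol=1e-5)

    def test_profile_optimum_beats_perturbations(self, rng):
        from ctradiomics.mlm import (_factorize_groups, _loglike_at,
                                     _suffstats)
        y, X, groups = simulate(rng)
        fit = fit_mlm(y, X, groups)
        idx, G = _factorize_groups(groups)
        st = _suffstats(np.asarray(y), X.to_numpy(), idx, G)
        lam_hat = fit.sigma2_patient / fit.sigma2_resid
        ll_hat = _loglike_at(max(lam_hat, 1e-12), st, reml=True)
        for f in np.exp(rng.normal(0, 1, 100)):
            assert _loglike_at(max(lam_hat * f, 1e-12), st, reml=True) <= ll_hat + 1e-8

    def test_singular_design_rejected(self, rng):
        y, X, groups = simulate(rng)
        X["dup"] = X["x"]
        with pytest.raises(ValueError, match="singular"):
            fit_mlm(y, X, groups)

    def test_single_group_rejected(self, rng):
        y, X, _ = simulate(rng)
        with pytest.raises(ValueError, match="2 groups"):
            fit_mlm(y, X, np.zeros(len(y)))


class TestMarginalR2:
    def test_direct_formula(self):
        # Var(X beta)=3, sigma2_patient=1, sigma2_resid=1 -> 0.6
        n = 1000
        fitted = np.sqrt(3.0 / 1.0) * np.linspace(-1, 1, n) * np.sqrt(
            1.0 / np.var(np.linspace(-1, 1, n), ddof=1))
        fit = MLMFit(
            params=np.array([1.0]), bse=np.array([0.1]),
            tvalues=np.array([10.0]), df=np.array([10.0]),
            pvalues=np.array([0.0]), sigma2_patient=1.0, sigma2_resid=1.0,
            loglike=0.0, loglike_ml=0.0, loglike_reml=0.0, method="REML",
            exog_names=["x"], n_obs=n, n_groups=5, fittedvalues=fitted,
            resid=np.zeros(n),
        )
        assert marginal_r2(fit) == pytest.approx(0.6, abs=1e-12)

    def test_intercept_only_model_is_zero(self, rng):
        y, X, groups = simulate(rng)
        fit = fit_mlm(y, X[["intercept"]], groups)
        assert marginal_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_tends_to_one(self, rng):
        y, X, groups = simulate(rng, s_b=0.0, s_e=1e-6)
        fit = fit_mlm(y, X, groups)
        assert marginal_r2(fit) > 0.999


class TestLRT:
    def test_identical_models_give_zero(self, rng):
        y, X, groups = simulate(rng)
        Xplus = X.copy()
        Xplus["z"] = rng.normal(size=len(y))
        full = fit_mlm(y, Xplus, groups, method="ML")
        restricted = fit_mlm(y, X, groups, method="ML")
        res = lrt(full, restricted)
        assert res.df == 1
        assert res.statistic >= -1e-6
        assert 0 <= res.pvalue <= 1

    def test_chi2_quantile(self):
        # df=1, statistic 3.841 -> p = 0.05
        assert stats.chi2.sf(3.841458820694124, 1) == pytest.approx(0.05)

    def test_reml_fits_rejected(self, rng):
        y, X, groups = simulate(rng)
        Xplus = X.copy()
        Xplus["z"] = rng.normal(size=len(y))
        with pytest.raises(ValueError, match="REML"):
            lrt(fit_mlm(y, Xplus, groups), fit_mlm(y, X, groups))

    def test_statistic_nonnegative_on_random_nested_models(self, rng):
        # nesting guarantees ll_full >= ll_restricted at the ML optimum
        for _ in range(60):
            y, X, groups = simulate(rng, G=8, m=4)
            Xplus = X.copy()
            Xplus["z"] = rng.normal(size=len(y))
            res = lrt(fit_mlm(y, Xplus, groups, method="ML", compute_df=False),
                      fit_mlm(y, X, groups, method="ML", compute_df=False))
            assert res.statistic >= -1e-6

    def test_statistic_grows_with_signal(self, rng):
        stats_ = []
        for n_per in (4, 8, 16):
            G = 10
            groups = np.repeat(np.arange(G), n_per)
            z = rng.normal(size=G * n_per)
            y = 0.8 * z + rng.normal(0, 1, G * n_per)
            X = pd.DataFrame({"intercept": np.ones(G * n_per)})
            Xf = X.copy()
            Xf["z"] = z
            res = lrt(fit_mlm(y, Xf, groups, method="ML", compute_df=False),
                      fit_mlm(y, X, groups, method="ML", compute_df=False))
            stats_.append(res.statistic)
        assert stats_[0] < stats_[1] < stats_[2]


class TestRobust:
    def test_clean_data_close_to_reml(self, rng):
        y, X, groups = simulate(rng)
        reml = fit_mlm(y, X, groups)
        rob = fit_robust_mlm(y, X, groups)
        assert rob.method == "robust"
        assert np.all(np.abs(rob.params - reml.params) < 2 * reml.bse)
        # non-outlying rows keep weights essentially 1
        assert np.median(rob.weights) == pytest.approx(1.0)

    def test_gross_outlier_damped(self):
        # contamination simulation: one +10 s.d. response outlier at a
        # high-leverage row; the robust slope shift should typically stay
        # below a quarter of the naive REML shift
        ratios = []
        for s in range(10):
            rng = np.random.default_rng(s)
            G, m = 10, 6
            n = G * m
            groups = np.repeat(np.arange(G), m)
            x = rng.normal(size=n)
            b = rng.normal(0, 0.8, G)
            y = 1.0 + 0.5 * x + b[groups] + rng.normal(0, 0.6, n)
            X = pd.DataFrame({"intercept": np.ones(n), "x": x})
            clean = fit_mlm(y, X, groups)
            sd = np.sqrt(clean.sigma2_patient + clean.sigma2_resid)
            i = int(np.argmax(np.abs(x)))
            y_bad = y.copy()
            y_bad[i] += 10 * sd
            naive = abs(fit_mlm(y_bad, X, groups).params[1] - clean.params[1])
            rob_fit = fit_robust_mlm(y_bad, X, groups)
            ratios.append(abs(rob_fit.params[1] - clean.params[1]) / naive)
            assert rob_fit.weights[i] < 0.5  # the outlier is down-weighted
        assert np.median(ratios) < 0.25
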