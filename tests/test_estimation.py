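"""FIML likelihood, optimizer, standard errors and reference fits."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import lcspanel as L
from lcspanel.estimation import (
    DataContractError,
    PanelDataset,
    baseline_fit,
    fiml_loglik,
    fit_model,
    observed_information_se,
    saturated_fit,
)
from lcspanel.model_core import ParameterTable, VariableSet


def _mvn_params(p, seed=0):
    rng = np.random.default_rng(seed)
    mu = rng.normal(0, 2, p)
    A = rng.normal(0, 1, (p, p))
    sigma = A @ A.T + p * np.eye(p)
    return mu, sigma


class TestFimlLoglik:
    def test_complete_data_equals_full_mvn_density(self):
        mu, sigma = _mvn_params(4)
        Y = stats.multivariate_normal.rvs(mu, sigma, size=50, random_state=1)
        expected = stats.multivariate_normal.logpdf(Y, mu, sigma).sum()
        assert fiml_loglik(Y, mu, sigma) == pytest.approx(expected, rel=1e-12)

    def test_single_observation_at_mean_unit_variance(self):
        y = np.array([[2.5, np.nan]])
        mu = np.array([2.5, 0.0])
        sigma = np.eye(2)
        assert fiml_loglik(y, mu, sigma) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_two_pattern_data_matches_per_row_oracle(self):
        """Pattern-grouped FIML equals a naive per-row subsetting oracle."""
        mu, sigma = _mvn_params(5, seed=3)
        rng = np.random.default_rng(7)
        Y = stats.multivariate_normal.rvs(mu, sigma, size=80, random_state=2)
        Y[40:, 3:] = np.nan  # half complete, half missing the last two
        expected = 0.0
        for row in Y:
            obs = ~np.isnan(row)
            expected += stats.multivariate_normal.logpdf(
                row[obs], mu[obs], sigma[np.ix_(obs, obs)]
            )
        assert fiml_loglik(Y, mu, sigma) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_row_order(self):
        mu, sigma = _mvn_params(4, seed=5)
        Y = stats.multivariate_normal.rvs(mu, sigma, size=60, random_state=4)
        rng = np.random.default_rng(0)
        Y[rng.random(60) < 0.4, 2:] = np.nan
        shuffled = Y[rng.permutation(60)]
        assert fiml_loglik(Y, mu, sigma) == pytest.approx(
            fiml_loglik(shuffled, mu, sigma), rel=1e-12
        )

    def test_non_pd_sigma_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            fiml_loglik(np.zeros((3, 2)), np.zeros(2), -np.eye(2))


class TestPanelDataset:
    def test_contract_validation(self, cohort):
        bad = cohort.frame.copy()
        bad.loc[bad.index[0], "voc_t1"] = np.nan
        with pytest.raises(DataContractError, match="wave-1"):
            PanelDataset(bad)
        bad2 = cohort.frame.copy()
        bad2.loc[bad2.index[0], "interval"] = -1.0
        if not np.isnan(bad2.loc[bad2.index[0], "voc_t2"]):
            with pytest.raises(DataContractError, match="interval"):
                PanelDataset(bad2)

    def test_csv_round_trip(self, cohort, tmp_path):
        path = tmp_path / "panel.csv"
        cohort.to_csv(path)
        back = PanelDataset.from_csv(path)
        assert np.allclose(
            back.frame[["voc_t1", "voc_t2"]].to_numpy(),
            cohort.frame[["voc_t1", "voc_t2"]].to_numpy(),
            equal_nan=True,
        )


class TestFitModel:
    def test_saturated_spec_recovers_sample_moments(self):
        """Fitting an all-free spec to complete data reproduces the sample
        means and ML covariance, and the closed-form saturated loglik."""
        mu, sigma = _mvn_params(3, seed=8)
        Y = stats.multivariate_normal.rvs(mu, sigma, size=120, random_state=6)
        v = VariableSet(("a", "b", "c"))
        t = ParameterTable(v)
        for x in v.names:
            t.cov(x, value=1.0, label=f"v_{x}")
            t.mean(x, label=f"m_{x}")
        t.cov("a", "b", label="c_ab")
        t.cov("a", "c", label="c_ac")
        t.cov("b", "c", label="c_bc")
        fit = fit_model(t, Y, L.FitOptions(n_starts=1))
        sat = saturated_fit(Y)
        assert fit.converged
        assert fit.loglik == pytest.approx(sat.loglik, abs=1e-6)
        for j, x in enumerate(v.names):
            assert fit.estimate(f"m_{x}") == pytest.approx(Y[:, j].mean(), abs=1e-6)
            assert fit.estimate(f"v_{x}") == pytest.approx(Y[:, j].var(), rel=1e-6)

    def test_regression_submodel_matches_ols_closed_form(self):
        """A single regression path reproduces OLS slope/intercept and the
        ML (1/n) residual variance on complete data."""
        rng = np.random.default_rng(11)
        n = 300
        x = rng.normal(0, 3, n)
        y = 2.0 + 0.8 * x + rng.normal(0, 1.5, n)
        v = VariableSet(("x", "y"))
        t = ParameterTable(v)
        t.path("x", "y", label="slope")
        t.cov("x", value=1.0, label="x_var")
        t.cov("y", value=1.0, label="resid_var")
        t.mean("x", label="x_mean")
        t.mean("y", label="intercept")
        fit = fit_model(t, np.column_stack([x, y]), L.FitOptions(n_starts=1))
        X = np.column_stack([np.ones(n), x])
        beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_hat
        assert fit.converged
        assert fit.estimate("slope") == pytest.approx(beta_hat[1], rel=1e-6)
        assert fit.estimate("intercept") == pytest.approx(beta_hat[0], rel=1e-6)
        assert fit.estimate("resid_var") == pytest.approx(np.mean(resid**2), rel=1e-5)

    def test_large_sample_consistency_mutualism(self, preset):
        """Estimates on a large simulated cohort sit near the generating
        structural values (loose large-N sanity check; the tight 2% check
        runs at the acceptance scale)."""
        data = L.simulate_panel(replace(preset, missing_rate=0.0), 20_000, seed=17)
        spec = L.build_bivariate_lcs()
        fit = fit_model(spec, data, L.FitOptions(n_starts=1))
        truth = L.generating_theta(preset, spec)
        assert fit.converged
        for label in ("beta_voc", "beta_mat", "voc1_on_age", "voc1_resid_var"):
            assert fit.estimate(label) == pytest.approx(truth[label], rel=0.10)

    def test_deterministic_given_options(self, cohort):
        spec = L.build_bivariate_lcs()
        f1 = fit_model(spec, cohort, L.FitOptions(n_starts=2, seed=9))
        f2 = fit_model(spec, cohort, L.FitOptions(n_starts=2, seed=9))
        assert np.array_equal(f1.theta, f2.theta)
        assert f1.loglik == f2.loglik

    def test_nested_extra_parameter_never_decreases_loglik(self, cohort):
        restricted = fit_model(L.build_bivariate_lcs({"mat_to_dvoc"}), cohort)
        general = fit_model(L.build_bivariate_lcs(), cohort)
        assert general.loglik >= restricted.loglik - 1e-6


class TestStandardErrors:
    def test_known_variance_normal_mean_model(self):
        """SE of a normal mean with fixed variance is sigma / sqrt(n)."""
        rng = np.random.default_rng(2)
        n, s2 = 400, 4.0
        y = rng.normal(1.0, np.sqrt(s2), (n, 1))
        t = ParameterTable(VariableSet(("y",)))
        t.cov("y", free=False, value=s2)
        t.mean("y", label="mu")
        fit = fit_model(t, y, L.FitOptions(n_starts=1))
        se = observed_information_se(fit, y)
        assert se[0] == pytest.approx(np.sqrt(s2 / n), rel=1e-4)

    def test_hessian_matches_finite_difference_of_loglik_oracle(self, preset):
        """The information Hessian (central differences of the analytic
        gradient) agrees entrywise with second differences of the
        log-likelihood values themselves."""
        data = L.simulate_panel(preset, 250, seed=23)
        spec = L.build_univariate_lcs("matrix")
        fit = fit_model(spec, data)
        _, H = observed_information_se(fit, data, return_hessian=True)
        Y = data.matrix(spec.variables.observed)
        theta = fit.theta

        def f(th):
            return fiml_loglik(Y, *L.implied_moments(L.assemble(spec, th)))

        k = theta.size
        H_oracle = np.zeros((k, k))
        h = 1e-4 * (np.abs(theta) + 0.05)
        for i in range(k):
            for j in range(i, k):
                tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                H_oracle[i, j] = H_oracle[j, i] = (
                    f(tpp) - f(tpm) - f(tmp) + f(tmm)
                ) / (4 * h[i] * h[j])
        scale = np.abs(H_oracle).max()
        assert np.allclose(H, H_oracle, rtol=1e-4, atol=1e-4 * scale)

    def test_information_se_agrees_with_bootstrap_oracle(self, preset):
        """Information-based SEs of the structural parameters track the
        spread of nonparametric bootstrap estimates."""
        data = L.simulate_panel(preset, 785, seed=31)
        spec = L.build_bivariate_lcs()
        fit = fit_model(spec, data, L.FitOptions(n_starts=1))
        se = observed_information_se(fit, data)
        rng = np.random.default_rng(100)
        frame = data.frame
        labels = ["beta_voc", "beta_mat", "gamma_voc_to_dmat", "gamma_mat_to_dvoc"]
        boots = []
        for _ in range(200):
            idx = rng.integers(0, len(frame), len(frame))
            bdata = PanelDataset(frame.iloc[idx].reset_index(drop=True))
            bfit = fit_model(spec, bdata, L.FitOptions(n_starts=1))
            boots.append([bfit.estimate(l) for l in labels])
        boot_sd = np.asarray(boots).std(axis=0, ddof=1)
        for label, bsd in zip(labels, boot_sd):
            info_se = se[fit.labels.index(label)]
            assert info_se == pytest.approx(bsd, rel=0.15)


class TestReferenceFits:
    def test_complete_data_saturated_closed_form(self):
        mu, sigma = _mvn_params(3, seed=12)
        Y = stats.multivariate_normal.rvs(mu, sigma, size=90, random_state=13)
        sat = saturated_fit(Y)
        m = Y.mean(axis=0)
        S = (Y - m).T @ (Y - m) / len(Y)
        assert np.allclose(sat.mu, m)
        assert np.allclose(sat.sigma, S)
        # closed-form saturated loglik: -n/2 (p log 2pi + log|S| + p)
        n, p = Y.shape
        expected = -0.5 * n * (p * np.log(2 * np.pi) + np.linalg.slogdet(S)[1] + p)
        assert sat.loglik == pytest.approx(expected, rel=1e-12)

    def test_em_saturated_dominates_model_fits(self, cohort):
        sat = saturated_fit(cohort)
        for spec in (L.build_bivariate_lcs(), L.build_g_model()):
            fit = fit_model(spec, cohort, L.FitOptions(n_starts=1))
            assert fit.loglik <= sat.loglik + 1e-6

    def test_baseline_never_beats_saturated(self, cohort):
        assert baseline_fit(cohort).loglik <= saturated_fit(cohort).loglik

    def test_null_chi_square_of_independent_variables(self):
        """On independently generated variables, the baseline-versus-
        saturated chi-square is near its df in expectation."""
        rng = np.random.default_rng(77)
        reps, n, p = 200, 120, 3
        Ts = []
        for _ in range(reps):
            Y = rng.normal(0, 1, (n, p))
            sat = saturated_fit(Y)
            base = baseline_fit(Y)
            Ts.append(2 * (sat.loglik - base.loglik))
        df = p * (p - 1) / 2
        # mean of chi2(df) is df; MC error ~ sqrt(2 df / reps)
        assert np.mean(Ts) == pytest.approx(df, abs=4 * np.sqrt(2 * df / reps))
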