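"""DIC / WAIC / CPO / PIT identities against independent brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

import ncdmap as nm
from ncdmap.diagnostics import (
    DiagnosticsError,
    compute_cpo,
    compute_dic,
    compute_pit,
    compute_waic,
    loo_predictive,
    run_diagnostics,
)


@pytest.fixture(scope="module")
def loglik_matrix():
    rng = np.random.default_rng(0)
    return rng.normal(-3.0, 0.5, size=(300, 25))


class TestDic:
    def test_degenerate_posterior(self):
        dic, p_d = compute_dic(np.full(200, 12.5), 12.5)
        assert p_d == 0.0 and dic == 12.5

    def test_brute_force_recomputation(self, loglik_matrix):
        dev = -2.0 * loglik_matrix.sum(axis=1)
        dev_at_mean = dev.mean() - 7.0
        dic, p_d = compute_dic(dev, dev_at_mean)
        # naive loop oracle
        dbar = sum(dev) / len(dev)
        assert p_d == pytest.approx(dbar - dev_at_mean, rel=1e-12)
        assert dic == pytest.approx(2 * dbar - dev_at_mean, rel=1e-12)

    def test_normal_normal_effective_parameters(self):
        # conjugate toy: y ~ N(theta, 1), theta ~ N(0, 1); posterior
        # N(y*n/(n+1), 1/(n+1)); p_D has closed form n/(n+1) per obs
        rng = np.random.default_rng(1)
        n, S = 40, 40_000
        y = rng.normal(0.0, np.sqrt(2.0), n)
        post_mean = y * (1.0 / 2.0)
        theta = post_mean[None, :] + rng.normal(0, np.sqrt(0.5), (S, n))
        ll = stats.norm.logpdf(y[None, :], theta, 1.0)
        dev = -2.0 * ll.sum(axis=1)
        eta_mean = theta.mean(axis=0)
        dev_at_mean = -2.0 * stats.norm.logpdf(y, eta_mean, 1.0).sum()
        _, p_d = compute_dic(dev, dev_at_mean)
        assert p_d == pytest.approx(n * 0.5, rel=0.1)

    def test_nonfinite_rejected(self):
        with pytest.raises(DiagnosticsError):
            compute_dic(np.r_[np.full(199, 1.0), np.inf], 1.0)


class TestWaic:
    def test_single_draw(self):
        ll = np.array([[-1.0, -2.0, -3.0]])
        waic, p_waic, lppd = compute_waic(ll)
        assert p_waic == 0.0
        assert waic == pytest.approx(-2 * ll.sum())

    def test_high_precision_oracle_five_rows(self):
        rng = np.random.default_rng(2)
        ll = rng.normal(-2.0, 0.7, size=(500, 5))
        waic, p_waic, lppd = compute_waic(ll)
        # independent accumulation with math.fsum and explicit means
        lppd_o = 0.0
        p_o = 0.0
        S = ll.shape[0]
        for r in range(5):
            col = ll[:, r]
            lppd_o += math.log(math.fsum(math.exp(v) for v in col) / S)
            mean = math.fsum(col) / S
            p_o += math.fsum((v - mean) ** 2 for v in col) / (S - 1)
        assert lppd == pytest.approx(lppd_o, rel=1e-10)
        assert p_waic == pytest.approx(p_o, rel=1e-10)
        assert waic == pytest.approx(-2 * (lppd_o - p_o), rel=1e-10)

    def test_row_constant_shift_moves_lppd_not_pwaic(self, loglik_matrix):
        waic0, p0, l0 = compute_waic(loglik_matrix)
        shifted = loglik_matrix.copy()
        shifted[:, 3] += 0.7  # same constant added to every draw of one row
        waic1, p1, l1 = compute_waic(shifted)
        assert l1 == pytest.approx(l0 + 0.7, rel=1e-10)
        assert p1 == pytest.approx(p0, rel=1e-10)


class TestCpo:
    def test_constant_likelihood_is_exact(self):
        ll = np.full((500, 4), math.log(0.2))
        cpo, lcpo, fails = compute_cpo(ll)
        np.testing.assert_allclose(cpo, 0.2, rtol=1e-12)
        assert lcpo == pytest.approx(4 * math.log(0.2), rel=1e-12)
        assert fails == 0

    def test_two_draw_harmonic_closed_form(self):
        a, b = 0.3, 0.05
        ll = np.log(np.array([[a], [b]]))
        cpo, _, _ = compute_cpo(ll, weight_threshold=1.0)
        assert cpo[0] == pytest.approx(2 * a * b / (a + b), rel=1e-12)

    def test_weight_concentration_counted_as_failure(self):
        ll = np.log(np.array([[1e-8], [0.5], [0.5]]))
        _, _, fails = compute_cpo(ll)
        assert fails == 1

    def test_conjugate_loo_predictive_closed_form(self):
        # y ~ N(theta, 1), theta ~ N(0, 10): leave-one-out predictive of y_i
        # has closed form; harmonic CPO from exact posterior draws matches
        rng = np.random.default_rng(3)
        n, S = 8, 400_000
        prior_var = 10.0
        y = rng.normal(0, np.sqrt(prior_var + 1.0), n)
        post_var = 1.0 / (n + 1.0 / prior_var)
        post_mean = post_var * y.sum()
        theta = rng.normal(post_mean, np.sqrt(post_var), S)
        ll = stats.norm.logpdf(y[None, :], theta[:, None], 1.0)
        cpo, _, _ = compute_cpo(ll)
        for i in range(n):
            v_i = 1.0 / (n - 1 + 1.0 / prior_var)
            m_i = v_i * (y.sum() - y[i])
            exact = stats.norm.pdf(y[i], m_i, np.sqrt(v_i + 1.0))
            assert cpo[i] == pytest.approx(exact, rel=0.05)

    def test_brute_force_identity(self, loglik_matrix):
        cpo, lcpo, _ = compute_cpo(loglik_matrix)
        S = loglik_matrix.shape[0]
        for r in range(0, 25, 5):
            inv = np.exp(-loglik_matrix[:, r])
            assert cpo[r] == pytest.approx(1.0 / inv.mean(), rel=1e-10)
        assert lcpo == pytest.approx(np.log(cpo).sum(), rel=1e-12)


class TestPit:
    def test_observation_above_all_draws_approaches_one(self):
        mu = np.full((200, 1), 5.0)
        pit = compute_pit(mu, [60.0], weighting="posterior")
        assert pit[0] > 0.999999

    def test_median_observation_near_half(self):
        mu = np.full((200, 1), 400.0)
        pit = compute_pit(mu, [400.0], weighting="posterior")
        assert pit[0] == pytest.approx(0.5, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compute_pit(np.zeros((0, 3)), [1, 2, 3], weighting="posterior")

    def test_loo_weighting_requires_loglik(self):
        with pytest.raises(ValueError):
            compute_pit(np.ones((10, 2)), [1, 2])


class TestFittedModelDiagnostics:
    def test_report_identities_and_invariants(self, std_panel, fitted_posterior):
        panel_std, _, _ = std_panel
        rep = run_diagnostics(panel_std, fitted_posterior)
        ll = fitted_posterior.loglik_draws
        # independent recomputation from the stored matrix
        S = ll.shape[0]
        lppd_o = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
        p_o = float(np.sum(ll.var(axis=0, ddof=1)))
        assert rep.lppd == pytest.approx(lppd_o, rel=1e-10)
        assert rep.waic == pytest.approx(-2 * (lppd_o - p_o), rel=1e-10)
        dev = -2.0 * ll.sum(axis=1)
        assert rep.dic == pytest.approx(
            2 * dev.mean()
            + 2.0 * nm.poisson_loglik(panel_std.y, panel_std.expected,
                                      fitted_posterior.eta_draws.mean(axis=0))[0],
            rel=1e-10,
        )
        assert rep.lcpo <= rep.lppd
        assert rep.p_waic >= 0
        assert rep.p_d >= 0
        assert np.all((rep.pit >= 0) & (rep.pit <= 1))
        assert rep.cpo_failures >= 0

    def test_observed_vs_fitted_table_shape(self, std_panel, fitted_posterior):
        panel_std, _, _ = std_panel
        rep = run_diagnostics(panel_std, fitted_posterior)
        assert len(rep.fitted) == panel_std.n_rows
        # fitted means land near observed for a well-specified model
        ratio = rep.fitted["fitted_mean"] / np.maximum(rep.fitted["observed"], 1)
        assert np.median(np.abs(np.log(ratio))) < 0.05

    def test_null_model_fit_has_fitted_mean_E(self, std_panel):
        # with all variances pinned to ~0 the fitted mean collapses to E
        panel_std, _, _ = std_panel
        spec = nm.ModelSpec(nm.build_eac_graph(), panel_std.diseases,
                            panel_std.years, panel_std.covariates,
                            components=("alpha", "psi"))
        big = nm.Hyperparameters(tau_alpha=1e10, tau_psi=1e10)
        cfg = nm.InferenceConfig(seed=4, iterations=500, burn_in=100, thin=4)
        post = nm.sample_hyperparameters(panel_std, spec, cfg, fix_hyper=big)
        fitted, _ = nm.observed_vs_fitted(panel_std, post)
        np.testing.assert_allclose(fitted["fitted_mean"], panel_std.expected, rtol=1e-3)

    def test_loo_predictive_no_clamping_on_healthy_fit(self, std_panel, fitted_posterior):
        panel_std, _, _ = std_panel
        pit, cpo, clamped = loo_predictive(
            *fitted_posterior.cond_moments, panel_std.y, panel_std.expected
        )
        assert clamped == 0
        assert np.all(cpo > 0)
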