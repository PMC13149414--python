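"""Laplace approximation, hyperparameter MCMC, summaries: correctness checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

import ncdmap as nm
from ncdmap.inference import InferenceConfig, summarize
from ncdmap.panel import validate_panel


def _single_cell_panel(y, E):
    df = pd.DataFrame(
        [{"country_id": "A", "year": 2000, "disease": "d", "deaths": y,
          "population": 1e6, "asmr": E / 1e6 * 1e5}]
    )
    return validate_panel(df)


def _psi_only_spec(countries, years, diseases=("d",)):
    return nm.ModelSpec(None, list(diseases), years, [], components=("psi",),
                        countries=countries)


def _poisson_lognormal_posterior(y, E, sigma):
    """Quadrature truth for a single Poisson cell with N(0, sigma^2) log-risk.

    Integrates on a window around the posterior mode (found by bisection on
    the score) so narrow high-count posteriors are resolved.
    """
    from scipy.optimize import brentq

    tau = 1.0 / sigma**2
    mode = brentq(lambda e: y - E * np.exp(e) - tau * e, -30, 30)
    sd0 = 1.0 / np.sqrt(E * np.exp(mode) + tau)
    lo, hi = mode - 12 * sd0, mode + 12 * sd0

    def logf(e):
        return y * (np.log(E) + e) - E * np.exp(e) - 0.5 * tau * e * e

    shift = logf(mode)
    unnorm = lambda e: np.exp(logf(e) - shift)
    den = quad(unnorm, lo, hi, limit=200)[0]
    mean = quad(lambda e: e * unnorm(e), lo, hi, limit=200)[0] / den
    second = quad(lambda e: e * e * unnorm(e), lo, hi, limit=200)[0] / den
    return mean, np.sqrt(second - mean**2)


class TestLaplace:
    def test_gaussian_likelihood_equals_gls_solution(self, toy_panel_2x2x2):
        # Laplace is exact for Gaussian targets: mode == GLS estimate
        graph, panel, _ = toy_panel_2x2x2
        panel_std, _ = nm.standardize_covariates(panel)
        spec = nm.ModelSpec(graph, panel.diseases, panel.years, panel.covariates)
        hyper = nm.Hyperparameters(tau_psi=4.0)
        sd = 0.5
        lap, model = nm.laplace_latent(hyper, panel_std, spec, likelihood="gaussian",
                                       gaussian_sd=sd)
        # direct dense GLS on the joint (w, psi) coordinates
        n, m = model.n, model.m_w
        Qw, _ = model.Qw_dense(hyper)
        A = np.hstack([model.X, np.eye(n)])
        Qprior = np.zeros((m + n, m + n))
        Qprior[:m, :m] = Qw
        Qprior[m:, m:] = np.diag(model.psi_precisions(hyper))
        H = Qprior + A.T @ A / sd**2
        sol = np.linalg.solve(H, A.T @ panel_std.y / sd**2)
        np.testing.assert_allclose(np.concatenate([lap.w, lap.psi]), sol, atol=1e-10)

    def test_single_cell_matches_quadrature_within_2pct(self):
        y, E, sigma = 25, 5.0, 0.7
        panel = _single_cell_panel(y, E)
        spec = _psi_only_spec(["A"], [2000])
        lap, _ = nm.laplace_latent(
            nm.Hyperparameters(tau_psi=1 / sigma**2), panel, spec
        )
        mean_true, _ = _poisson_lognormal_posterior(y, E, sigma)
        assert abs(lap.psi[0] - mean_true) / abs(mean_true) < 0.02

    def test_laplace_sd_tightens_with_count(self):
        sigma = 0.7
        sds = []
        for y in (5, 25, 100, 400):
            panel = _single_cell_panel(y, 5.0)
            spec = _psi_only_spec(["A"], [2000])
            lap, _ = nm.laplace_latent(
                nm.Hyperparameters(tau_psi=1 / sigma**2), panel, spec
            )
            lap_sd = 1.0 / np.sqrt(lap.Dw[0])
            _, sd_true = _poisson_lognormal_posterior(y, 5.0, sigma)
            assert lap_sd == pytest.approx(sd_true, rel=0.1)
            sds.append(lap_sd)
        assert all(np.diff(sds) < 0)

    def test_objective_trace_monotone(self, std_panel, full_spec):
        panel_std, _, truth = std_panel
        lap, _ = nm.laplace_latent(truth.hyper, panel_std, full_spec)
        assert all(np.diff(lap.trace) >= 0)


class TestSampler:
    def test_fixed_seed_bitwise_reproducible(self, std_panel, full_spec):
        panel_std, _, _ = std_panel
        cfg = InferenceConfig(seed=5, iterations=120, burn_in=40, thin=2)
        p1 = nm.sample_hyperparameters(panel_std, full_spec, cfg)
        p2 = nm.sample_hyperparameters(panel_std, full_spec, cfg)
        pd.testing.assert_frame_equal(p1.hyper_draws, p2.hyper_draws)
        np.testing.assert_array_equal(p1.eta_draws, p2.eta_draws)

    def test_conjugate_normal_normal_precision_posterior(self):
        # y_i = psi_i + e_i with known obs sd; evidence is available in
        # closed form, so the sampled tau posterior must match it (KS < 0.05)
        rng = np.random.default_rng(10)
        n, sd_obs, tau_true = 60, 1.0, 1.0
        y = rng.normal(0, np.sqrt(1 / tau_true + sd_obs**2), n)
        # centered Gaussian observations: built directly (the non-negative
        # integer count rule is a Poisson-panel invariant, not a Gaussian one)
        df = pd.DataFrame(
            {
                "country_id": "A",
                "year": np.arange(2000, 2000 + n),
                "disease": "d",
                "deaths": y,
                "population": 1e6,
                "asmr": 10.0,
                "expected_deaths": 1.0,
            }
        )
        panel = nm.MortalityPanel(df, covariates=[])
        spec = _psi_only_spec(["A"], list(range(2000, 2000 + n)))
        cfg = InferenceConfig(seed=2, iterations=10_500, burn_in=500, thin=2)
        post = nm.sample_hyperparameters(panel, spec, cfg, likelihood="gaussian",
                                         gaussian_sd=sd_obs)
        draws = post.hyper_draws["tau_psi"].to_numpy()
        assert len(draws) == 5000

        # the posterior has a tau^(-3/2) right tail (prior-dominated), so the
        # closed-form CDF is accumulated on a log-scale grid
        prior = spec.precision_priors["psi"]
        logtaus = np.linspace(np.log(draws.min()) - 1, np.log(draws.max()) + 1, 40_000)
        taus = np.exp(logtaus)
        logpost = prior.logpdf(taus) + np.sum(
            stats.norm.logpdf(y[:, None], 0.0, np.sqrt(1 / taus + sd_obs**2)[None, :]),
            axis=0,
        )
        dens = np.exp(logpost - logpost.max()) * taus  # d tau = tau d log tau
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        ks = stats.ks_1samp(draws, lambda x: np.interp(np.log(x), logtaus, cdf))
        assert ks.statistic < 0.05

    def test_acceptance_rate_recorded_and_sane(self, fitted_posterior):
        acc = fitted_posterior.metadata["acceptance_rate"]
        assert 0.05 <= acc <= 0.95
        assert fitted_posterior.metadata["seed"] == 11

    def test_exchangeability_of_laplace_mode_under_relabeling(self, std_panel):
        # renaming countries (panel + graph together) permutes the shared
        # spatial mode identically
        panel_std, _, truth = std_panel
        spec = nm.ModelSpec(nm.build_eac_graph(), panel_std.diseases,
                            panel_std.years, panel_std.covariates)
        lap, model = nm.laplace_latent(truth.hyper, panel_std, spec)
        _, lat = model.state_from_w(lap.w, lap.psi)

        mapping = {c: f"Z{k}" for k, c in enumerate(reversed(panel_std.countries))}
        df = panel_std.df.copy()
        df["country_id"] = df["country_id"].map(mapping)
        panel_perm = validate_panel(df)
        graph_perm = nm.CountryGraph(
            sorted(mapping.values()),
            [(mapping[a], mapping[b]) for a, b in nm.build_eac_graph().edges],
        )
        spec_perm = nm.ModelSpec(graph_perm, panel_perm.diseases,
                                 panel_perm.years, panel_perm.covariates)
        lap2, model2 = nm.laplace_latent(truth.hyper, panel_perm, spec_perm)
        _, lat2 = model2.state_from_w(lap2.w, lap2.psi)
        for old_label, lam_val in zip(panel_std.countries, lat.lam):
            new_ix = panel_perm.countries.index(mapping[old_label])
            assert lat2.lam[new_ix] == pytest.approx(lam_val, abs=1e-6)

    def test_tau_recovery_within_factor_two(self):
        # pooled across the six precisions over seeded replicates
        taus = ["tau_alpha", "tau_lambda", "tau_u", "tau_phi", "tau_v", "tau_psi"]
        truth = nm.simulate.default_true_hyper()
        hits = total = 0
        for r in range(8):
            panel, _ = nm.simulate_panel(nm.SimulationConfig(seed=8000 + r))
            ps, _ = nm.standardize_covariates(panel)
            spec = nm.ModelSpec(nm.build_eac_graph(), panel.diseases, panel.years,
                                panel.covariates)
            post = nm.sample_hyperparameters(
                ps, spec, InferenceConfig(seed=r, iterations=500, burn_in=200, thin=3)
            )
            for t in taus:
                ratio = post.hyper_draws[t].mean() / getattr(truth, t)
                hits += int(0.5 < ratio < 2.0)
                total += 1
        assert hits / total >= 0.8

    def test_beta_bias_shrinks_with_longer_series(self):
        def mean_abs_err(T, reps, iters):
            errs = []
            for r in range(reps):
                panel, gt = nm.simulate_panel(nm.SimulationConfig(seed=9100 + r, n_years=T))
                ps, _ = nm.standardize_covariates(panel)
                spec = nm.ModelSpec(nm.build_eac_graph(), panel.diseases,
                                    panel.years, panel.covariates)
                post = nm.sample_hyperparameters(
                    ps, spec, InferenceConfig(seed=r, iterations=iters, burn_in=120, thin=3)
                )
                _, bd = post.draws_for("beta[")
                errs.append(np.abs(bd.mean(0) - gt.fixed.beta).mean())
            return float(np.mean(errs))

        assert mean_abs_err(80, 2, 300) < mean_abs_err(20, 3, 400)


class TestSummarize:
    def test_degenerate_draws(self):
        tab = summarize(np.full((200, 1), 3.14), ["c"])
        row = tab.iloc[0]
        assert row["mean"] == row["median"] == row["mode"] == pytest.approx(3.14)
        assert row["sd"] == 0.0

    def test_standard_normal_quantiles(self):
        draws = np.random.default_rng(0).standard_normal((100_000, 1))
        row = summarize(draws).iloc[0]
        assert row["q2.5"] == pytest.approx(-1.96, abs=0.02)
        assert row["q97.5"] == pytest.approx(1.96, abs=0.02)
        assert row["median"] == pytest.approx(0.0, abs=0.02)

    def test_quantile_equivariance_under_exp(self, fitted_posterior):
        eta = fitted_posterior.eta_draws[:, 0]
        theta = np.exp(eta)
        q_eta = np.percentile(eta, [2.5, 50, 97.5])
        q_theta = np.percentile(theta, [2.5, 50, 97.5])
        np.testing.assert_allclose(q_theta, np.exp(q_eta), rtol=0.02)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            summarize(np.zeros((50, 2)))
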