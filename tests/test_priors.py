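"""PC hyperpriors, BYM2 combination, constrained Gaussian sampling."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import ncdmap as nm
from ncdmap.priors import bym2_joint_precision, sample_constrained_gaussian


@pytest.fixture(scope="module")
def scaled_eac():
    return nm.scale_structure(nm.icar_structure(nm.build_eac_graph()))


class TestPCPrecisionPrior:
    def test_density_normalizes(self):
        p = nm.PCPrecisionPrior(U=1.0, alpha=0.01)
        val, _ = quad(lambda t: math.exp(p.logpdf(t)), 1e-12, np.inf, limit=300)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_tail_calibration(self):
        # P(sigma > U) = alpha, via quadrature on the tau scale:
        # sigma > U  <=>  tau < U**-2
        p = nm.PCPrecisionPrior(U=0.7, alpha=0.05)
        val, _ = quad(lambda t: math.exp(p.logpdf(t)), 1e-14, 0.7**-2, limit=300)
        assert val == pytest.approx(0.05, abs=1e-5)

    def test_logpdf_change_of_variables_oracle(self):
        # sigma ~ Exponential(lam); tau = sigma^-2 =>
        # p(tau) = lam * exp(-lam tau^-1/2) * |d sigma/d tau|
        p = nm.PCPrecisionPrior(U=1.0, alpha=0.01)
        lam = -math.log(0.01)
        tau = 1.0
        oracle = math.log(lam * math.exp(-lam * tau**-0.5) * 0.5 * tau**-1.5)
        assert p.logpdf(tau) == pytest.approx(oracle, rel=1e-12)

    def test_closed_form_sigma_cdf_matches_numeric(self):
        p = nm.PCPrecisionPrior(U=1.0, alpha=0.01)
        for s in np.linspace(0.1, 3.0, 15):
            numeric, _ = quad(lambda t: math.exp(p.logpdf(t)), 1e-14, s**-2, limit=300)
            assert abs(numeric - p.sigma_tail_prob(s)) < 1e-6

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nm.PCPrecisionPrior(U=-1.0, alpha=0.01)
        with pytest.raises(ValueError):
            nm.PCPrecisionPrior(U=1.0, alpha=1.5)
        with pytest.raises(ValueError):
            nm.PCPrecisionPrior().logpdf(-2.0)


class TestPCMixingPrior:
    def test_density_normalizes(self, scaled_eac):
        p = nm.PCMixingPrior(scaled_eac, U=0.5, alpha=2 / 3)
        val, _ = quad(lambda r: math.exp(p.logpdf(r)), 1e-9, 1 - 1e-9, limit=300)
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_distance_nondecreasing(self, scaled_eac):
        p = nm.PCMixingPrior(scaled_eac)
        grid = np.linspace(1e-6, 1 - 1e-9, 100)
        d = p.distance(grid)
        assert np.all(np.diff(d) >= -1e-12)

    def test_cdf_calibration_at_U(self, scaled_eac):
        p = nm.PCMixingPrior(scaled_eac, U=0.5, alpha=2 / 3)
        assert p.cdf(0.5) == pytest.approx(2 / 3, abs=1e-6)
        p2 = nm.PCMixingPrior(scaled_eac, U=0.3, alpha=0.5)
        assert p2.cdf(0.3) == pytest.approx(0.5, abs=1e-6)

    def test_requires_scaled_structure(self):
        raw = nm.icar_structure(nm.build_eac_graph())
        with pytest.raises(ValueError, match="scaled"):
            nm.PCMixingPrior(raw)


class TestBym2Combine:
    def test_boundaries_exact(self):
        rng = np.random.default_rng(0)
        u, v = rng.normal(size=7), rng.normal(size=7)
        tau = 2.0
        np.testing.assert_array_equal(nm.bym2_combine(0.0, tau, u, v), v / math.sqrt(tau))
        np.testing.assert_array_equal(nm.bym2_combine(1.0, tau, u, v), u / math.sqrt(tau))

    def test_marginal_variance_one_over_tau(self, scaled_eac):
        # 10,000 draws at rho=0.5, tau=2: geometric-mean marginal variance 1/tau
        rng = np.random.default_rng(1)
        n, reps, tau, rho = 7, 10_000, 2.0, 0.5
        C = np.ones((1, n))
        u = sample_constrained_gaussian(scaled_eac.Q, C, rng, size=reps)
        v = rng.standard_normal((reps, n))
        b = np.array([nm.bym2_combine(rho, tau, u[k], v[k]) for k in range(reps)])
        gm_var = np.exp(np.mean(np.log(b.var(axis=0))))
        mc_se = gm_var * math.sqrt(2.0 / reps) * 3
        assert abs(gm_var - 1 / tau) < 3 * math.sqrt(2.0 / reps) * (1 / tau) + mc_se

    @pytest.mark.parametrize("rho", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_generalized_variance_across_mixings(self, scaled_eac, rho):
        rng = np.random.default_rng(2)
        n, reps, tau = 7, 8_000, 1.5
        u = sample_constrained_gaussian(scaled_eac.Q, np.ones((1, n)), rng, size=reps)
        v = rng.standard_normal((reps, n))
        b = np.array([nm.bym2_combine(rho, tau, u[k], v[k]) for k in range(reps)])
        gm_var = np.exp(np.mean(np.log(b.var(axis=0))))
        assert gm_var == pytest.approx(1 / tau, rel=3 * math.sqrt(2.0 / reps) * 3)

    def test_domain_errors(self):
        u = np.zeros(3)
        with pytest.raises(ValueError):
            nm.bym2_combine(1.5, 1.0, u, u)
        with pytest.raises(ValueError):
            nm.bym2_combine(0.5, -1.0, u, u)
        with pytest.raises(ValueError):
            nm.bym2_combine(0.5, 1.0, u, np.zeros(4))


class TestConstrainedGaussian:
    def test_matches_conditioning_by_kriging_oracle(self):
        # 4-dim proper Gaussian, one sum-to-zero constraint: the subspace
        # covariance must equal the kriging-conditioned covariance exactly
        rng = np.random.default_rng(3)
        A = rng.normal(size=(4, 4))
        Q = A @ A.T + 4 * np.eye(4)
        C = np.ones((1, 4))
        from ncdmap.priors import constraint_null_basis

        B = constraint_null_basis(C, 4)
        cov_impl = B @ np.linalg.inv(B.T @ Q @ B) @ B.T
        S = np.linalg.inv(Q)
        cov_krig = S - S @ C.T @ np.linalg.inv(C @ S @ C.T) @ C @ S
        np.testing.assert_allclose(cov_impl, cov_krig, atol=1e-10)

    def test_draws_satisfy_constraints(self):
        rng = np.random.default_rng(4)
        sm = nm.scale_structure(nm.icar_structure(nm.build_eac_graph()))
        draws = sample_constrained_gaussian(sm.Q, np.ones((1, 7)), rng, size=200)
        assert np.abs(draws.sum(axis=1)).max() < 1e-8

    def test_empirical_covariance_matches(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(4, 4))
        Q = A @ A.T + 4 * np.eye(4)
        C = np.ones((1, 4))
        draws = sample_constrained_gaussian(Q, C, rng, size=40_000)
        from ncdmap.priors import constraint_null_basis

        B = constraint_null_basis(C, 4)
        cov_true = B @ np.linalg.inv(B.T @ Q @ B) @ B.T
        np.testing.assert_allclose(np.cov(draws.T), cov_true, atol=0.01)


class TestBym2JointPrecision:
    def test_positive_definite_on_constrained_subspace(self, scaled_eac):
        from ncdmap.priors import constraint_null_basis

        Q = bym2_joint_precision(0.4, 2.0, scaled_eac.Q)
        C = np.zeros((2, 14))
        C[0, :7] = 1.0
        C[1, 7:] = 1.0
        B = constraint_null_basis(C, 14)
        vals = np.linalg.eigvalsh(B.T @ Q @ B)
        assert vals.min() > 0

    def test_boundary_rho_rejected(self, scaled_eac):
        with pytest.raises(ValueError):
            bym2_joint_precision(1.0, 1.0, scaled_eac.Q)


class TestModelSpecConstraints:
    def test_constraint_sets(self, full_spec):
        cons = full_spec.build_constraints()
        assert set(cons) == {"lambda", "phi"} | {f"u:{d}" for d in full_spec.diseases} | {
            f"v:{d}" for d in full_spec.diseases
        }
        assert cons["lambda"].shape == (2, 14)
        assert cons["phi"].shape == (1, 20)

    def test_constrained_prior_draws_sum_to_zero(self, full_spec):
        rng = np.random.default_rng(6)
        h = nm.Hyperparameters()
        for b in full_spec.dense_blocks:
            if b.C is None:
                continue
            Qb = b.B.T @ b.Q_fn(h) @ b.B
            L = np.linalg.cholesky(np.linalg.inv(Qb))
            z = b.B @ (L @ rng.standard_normal(b.w_size))
            assert np.abs(b.C @ z).max() < 1e-8


class TestHyperparameters:
    def test_validation(self):
        with pytest.raises(ValueError):
            nm.Hyperparameters(tau_lambda=-1.0)
        with pytest.raises(ValueError):
            nm.Hyperparameters(rho_u=1.4)

    def test_roundtrip_through_spec_vector(self, full_spec):
        h = nm.Hyperparameters(tau_lambda=3.0, rho_lambda=0.7)
        vec = full_spec.hyper_to_vector(h)
        h2 = full_spec.hyper_from_vector(vec)
        assert h2.tau_lambda == pytest.approx(3.0)
        assert h2.rho_lambda == pytest.approx(0.7)
        t = full_spec.hyper_transform(vec)
        np.testing.assert_allclose(full_spec.hyper_untransform(t), vec, rtol=1e-12)
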