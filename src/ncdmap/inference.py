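"""Posterior computation for the latent Gaussian model.

Inference follows the classical two-level strategy for latent Gaussian
models: for each hyperparameter value the latent field (fixed effects plus
all random effects) is integrated out with a Laplace approximation built by
constrained Newton optimization, and the low-dimensional hyperparameter
posterior is explored with adaptive random-walk Metropolis on transformed
coordinates (log precisions, logit mixing parameters).  Latent draws are
generated from the Gaussian approximation at each retained hyperparameter
draw; an optional independence-Metropolis refresh step corrects the draws
toward the exact conditional when requested.

The Poisson likelihood with canonical link makes the latent target strictly
log-concave, so the Newton iteration (with step halving) increases the
log-posterior monotonically and converges quadratically.
"""

from __future__ import annotations

import dataclasses
import time
import warnings

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.stats import gaussian_kde

from .model import JointModel
from .modelspec import ModelSpec
from .panel import MortalityPanel
from .priors import Hyperparameters


class NewtonError(RuntimeError):
    """Newton optimization of the latent field failed to converge."""

    def __init__(self, message, trace):
        super().__init__(f"{message}; objective trace: {trace}")
        self.trace = trace


@dataclasses.dataclass
class InferenceConfig:
    """Sampler settings.  ``seed`` is mandatory for reproducibility."""

    seed: int
    iterations: int = 5000
    burn_in: int = 1000
    thin: int = 4
    target_accept: float = 0.35
    init_scale: float = 0.15
    latent_mcmc: bool = False
    latent_mcmc_steps: int = 20
    max_newton_iter: int = 100
    grad_tol: float = 1e-8
    step_tol: float = 1e-10

    @property
    def n_retained(self) -> int:
        return max(0, (self.iterations - self.burn_in)) // self.thin


@dataclasses.dataclass
class LaplaceResult:
    """Gaussian approximation of the latent field given hyperparameters."""

    w: np.ndarray          # dense-part mode (constrained basis coordinates)
    psi: np.ndarray | None  # interaction mode (per panel row)
    eta: np.ndarray
    objective: float        # loglik + latent log-prior quad terms at the mode
    log_evidence: float     # Laplace estimate of log p(y | hyper), up to const
    n_iter: int
    trace: list
    # pieces needed for sampling / density evaluation
    S_chol: tuple | None    # cho_factor of the dense Schur complement
    Dw: np.ndarray | None   # psi-block posterior precision diagonal (d + W)
    Wdiag: np.ndarray       # likelihood curvature at the mode
    Qw: np.ndarray
    d_psi: np.ndarray | None

    def marginal_sd_w(self) -> np.ndarray:
        """Posterior sd of the dense latent coordinates (from S^-1)."""
        if self.S_chol is None:
            return np.zeros(0)
        m = self.Qw.shape[0]
        inv = cho_solve(self.S_chol, np.eye(m))
        return np.sqrt(np.diag(inv))


def _laplace(model: JointModel, hyper: Hyperparameters, start=None,
             max_iter=100, gtol=1e-8, stol=1e-10) -> LaplaceResult:
    n, m = model.n, model.m_w
    Qw, logdet_Qw = model.Qw_dense(hyper) if m else (np.zeros((0, 0)), 0.0)
    d = model.psi_precisions(hyper) if model.has_psi else None

    w = np.zeros(m)
    psi = np.zeros(n) if model.has_psi else None
    if start is not None:
        w0, psi0 = start
        if w0 is not None and w0.shape == (m,):
            w = w0.copy()
        if model.has_psi and psi0 is not None:
            psi = psi0.copy()

    def objective(w_, psi_):
        eta = model.eta(w_, psi_)
        ll, _ = model.obs.loglik(eta)
        val = ll - 0.5 * (w_ @ Qw @ w_ if m else 0.0)
        if model.has_psi:
            val -= 0.5 * float(np.sum(d * psi_**2))
        return val, eta

    f, eta = objective(w, psi)
    trace = [f]
    S_cho = None
    Wdiag = None
    for it in range(max_iter):
        g_eta, Wdiag = model.obs.grad_hess(eta)
        grad_w = (model.X.T @ g_eta - Qw @ w) if m else np.zeros(0)
        grad_psi = (g_eta - d * psi) if model.has_psi else None
        gmax = max(
            np.abs(grad_w).max() if m else 0.0,
            np.abs(grad_psi).max() if model.has_psi else 0.0,
        )
        if gmax < gtol:
            break

        if model.has_psi:
            Dw = d + Wdiag
            ratio = Wdiag * d / Dw  # W - W (D+W)^-1 W
            if m:
                S = Qw + (model.X * ratio[:, None]).T @ model.X
                S_cho = cho_factor(S, lower=False)
                rhs = grad_w - model.X.T @ (Wdiag / Dw * grad_psi)
                dw = cho_solve(S_cho, rhs)
                dpsi = (grad_psi - Wdiag * (model.X @ dw)) / Dw
            else:
                dw = np.zeros(0)
                dpsi = grad_psi / Dw
        else:
            S = Qw + (model.X * Wdiag[:, None]).T @ model.X
            S_cho = cho_factor(S, lower=False)
            dw = cho_solve(S_cho, grad_w)
            dpsi = None

        full_step = max(
            np.abs(dw).max() if m else 0.0,
            np.abs(dpsi).max() if model.has_psi else 0.0,
        )
        if full_step < stol:
            break

        # step halving: never decrease the objective
        t = 1.0
        while True:
            w_new = w + t * dw if m else w
            psi_new = psi + t * dpsi if model.has_psi else None
            f_new, eta_new = objective(w_new, psi_new)
            if f_new >= f or t < 1e-10:
                break
            t *= 0.5
        ftol = 1e-9 * max(1.0, abs(f))
        if f_new < f - ftol:
            raise NewtonError("line search could not increase the log-posterior", trace)
        if f_new < f + ftol:
            # improvement at the floating-point floor: converged
            if f_new >= f:
                w, psi, f, eta = w_new, psi_new, f_new, eta_new
                trace.append(f)
            break
        step_norm = max(
            np.abs(t * dw).max() if m else 0.0,
            np.abs(t * dpsi).max() if model.has_psi else 0.0,
        )
        w, psi, f, eta = w_new, psi_new, f_new, eta_new
        trace.append(f)
        if step_norm < stol:
            break
    else:
        raise NewtonError(f"no convergence in {max_iter} Newton iterations", trace)

    # curvature at the mode (recompute so cached factors match the final iterate)
    _, Wdiag = model.obs.grad_hess(eta)
    logdet_post = 0.0
    if model.has_psi:
        Dw = d + Wdiag
        logdet_post += float(np.sum(np.log(Dw)))
        ratio = Wdiag * d / Dw
        if m:
            S = Qw + (model.X * ratio[:, None]).T @ model.X
            S_cho = cho_factor(S, lower=False)
            logdet_post += 2.0 * float(np.sum(np.log(np.diag(S_cho[0]))))
    else:
        Dw = None
        if m:
            S = Qw + (model.X * Wdiag[:, None]).T @ model.X
            S_cho = cho_factor(S, lower=False)
            logdet_post = 2.0 * float(np.sum(np.log(np.diag(S_cho[0]))))

    logdet_prior = logdet_Qw + (float(np.sum(np.log(d))) if model.has_psi else 0.0)
    log_ev = f + 0.5 * logdet_prior - 0.5 * logdet_post

    return LaplaceResult(
        w=w, psi=psi, eta=eta, objective=f, log_evidence=log_ev,
        n_iter=len(trace) - 1, trace=trace,
        S_chol=S_cho if m else None, Dw=Dw, Wdiag=Wdiag, Qw=Qw, d_psi=d,
    )


def laplace_latent(
    hyper: Hyperparameters,
    panel: MortalityPanel,
    spec: ModelSpec,
    start=None,
    likelihood: str = "poisson",
    gaussian_sd: float = 1.0,
    max_iter: int = 100,
) -> tuple[LaplaceResult, JointModel]:
    """Laplace approximation (mode + curvature) of latent | hyper, data.

    Returns the approximation together with the bound :class:`JointModel`
    whose ``state_from_w`` maps the mode back to named effects.
    """
    model = JointModel(panel, spec, likelihood=likelihood, gaussian_sd=gaussian_sd)
    return _laplace(model, hyper, start=start, max_iter=max_iter), model


def _conditional_eta_moments(model: JointModel, lap: LaplaceResult):
    """Per-row conditional mean/variance of eta and likelihood curvature at
    the mode, for one hyperparameter value (used by leave-one-out checks)."""
    if model.m_w:
        Rt = solve_triangular(lap.S_chol[0].T, model.X.T, lower=True)
        q = (Rt**2).sum(axis=0)  # x_i' S^{-1} x_i
    else:
        q = np.zeros(model.n)
    if model.has_psi:
        v = (lap.d_psi / lap.Dw) ** 2 * q + 1.0 / lap.Dw
    else:
        v = q
    return lap.eta.copy(), v, lap.Wdiag.copy()


def _sample_latent(model: JointModel, lap: LaplaceResult, rng: np.random.Generator):
    """One draw from the Gaussian approximation N(mode, H^-1)."""
    m = model.m_w
    if m:
        zr = rng.standard_normal(m)
        dw = solve_triangular(lap.S_chol[0], zr, lower=False)
        w = lap.w + dw
    else:
        w = lap.w
        dw = np.zeros(0)
    if model.has_psi:
        mean_shift = (lap.Wdiag * (model.X @ dw)) / lap.Dw if m else 0.0
        psi = lap.psi - mean_shift + rng.standard_normal(model.n) / np.sqrt(lap.Dw)
    else:
        psi = None
    return w, psi


def _gauss_logq(model: JointModel, lap: LaplaceResult, w, psi):
    """Unnormalized log density of the Laplace Gaussian at (w, psi)."""
    dw = w - lap.w
    val = 0.0
    if model.m_w:
        Hww = lap.Qw + (model.X * (lap.Wdiag)[:, None]).T @ model.X
        val -= 0.5 * dw @ Hww @ dw
    if model.has_psi:
        dpsi = psi - lap.psi
        val -= 0.5 * float(np.sum(lap.Dw * dpsi**2))
        if model.m_w:
            val -= float(dpsi @ (lap.Wdiag * (model.X @ dw)))
    return val


def _latent_objective(model: JointModel, lap: LaplaceResult, w, psi):
    eta = model.eta(w, psi)
    ll, _ = model.obs.loglik(eta)
    val = ll - 0.5 * (w @ lap.Qw @ w if model.m_w else 0.0)
    if model.has_psi:
        val -= 0.5 * float(np.sum(lap.d_psi * psi**2))
    return val


def _refresh_latent(model, lap, w, psi, rng, steps):
    """Independence-Metropolis refresh targeting the exact conditional."""
    f_cur = _latent_objective(model, lap, w, psi) - _gauss_logq(model, lap, w, psi)
    acc = 0
    for _ in range(steps):
        w_p, psi_p = _sample_latent(model, lap, rng)
        f_prop = _latent_objective(model, lap, w_p, psi_p) - _gauss_logq(model, lap, w_p, psi_p)
        if np.log(rng.random()) < f_prop - f_cur:
            w, psi, f_cur = w_p, psi_p, f_prop
            acc += 1
    return w, psi, acc


class PosteriorResult:
    """Draws and summaries for fixed effects, latent components and hypers."""

    def __init__(self, spec, panel, hyper_draws, z_names, z_draws, eta_draws,
                 loglik_draws, metadata, cond_moments=None):
        self.spec = spec
        self.panel = panel
        self.hyper_draws = hyper_draws        # DataFrame, natural scale
        self.z_names = z_names                # dense z names + psi names
        self.z_draws = z_draws                # (ndraws, m_z [+ n])
        self.eta_draws = eta_draws            # (ndraws, n_rows)
        self.loglik_draws = loglik_draws      # (ndraws, n_rows)
        self.metadata = metadata
        #: per-retained-draw conditional (mode, variance, curvature) of eta
        #: given the hyperparameters — the Gaussian marginals the
        #: leave-one-out diagnostics subtract the likelihood from
        self.cond_moments = cond_moments

    @property
    def n_draws(self) -> int:
        return self.eta_draws.shape[0]

    @property
    def mu_draws(self) -> np.ndarray:
        """Posterior draws of the Poisson mean E * theta."""
        return self.panel.expected[None, :] * np.exp(self.eta_draws)

    def draws_for(self, prefix: str) -> tuple[list[str], np.ndarray]:
        idx = [k for k, nm in enumerate(self.z_names) if nm.startswith(prefix)]
        return [self.z_names[k] for k in idx], self.z_draws[:, idx]

    def summary(self, which: str = "main") -> pd.DataFrame:
        """Posterior summary table (mean, sd, quantiles, KDE mode).

        ``which`` is "main" (fixed effects + hyperparameters), "latent"
        (every latent scalar) or "all".
        """
        cols: list[str] = []
        mats: list[np.ndarray] = []
        if which in ("main", "all"):
            for prefix in ("beta[", "alpha["):
                nms, dr = self.draws_for(prefix)
                cols += nms
                mats.append(dr)
            cols += list(self.hyper_draws.columns)
            mats.append(self.hyper_draws.to_numpy())
        if which in ("latent", "all"):
            keep = [
                k
                for k, nm in enumerate(self.z_names)
                if not (nm.startswith("beta[") or nm.startswith("alpha["))
            ]
            cols += [self.z_names[k] for k in keep]
            mats.append(self.z_draws[:, keep])
        draws = np.hstack(mats)
        return summarize(draws, cols)

    def to_csv(self, path):
        """Draw archive: one column per scalar parameter path."""
        df = pd.DataFrame(self.z_draws, columns=self.z_names)
        for c in self.hyper_draws.columns:
            df[c] = self.hyper_draws[c].to_numpy()
        df.to_csv(path, index=False)


def _kde_mode(x: np.ndarray) -> float:
    sd = np.std(x)
    if sd < 1e-12:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def summarize(draws: np.ndarray, names=None) -> pd.DataFrame:
    """Posterior summary per scalar: mean, sd, 2.5/50/97.5%, KDE mode.

    Requires at least 100 retained draws per scalar.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] < 100:
        raise ValueError("need at least 100 draws to summarize")
    if names is None:
        names = [f"p{k}" for k in range(draws.shape[1])]
    q = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "parameter": list(names),
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0, ddof=1),
            "q2.5": q[0],
            "median": q[1],
            "q97.5": q[2],
            "mode": [_kde_mode(draws[:, k]) for k in range(draws.shape[1])],
        }
    )


def sample_hyperparameters(
    panel: MortalityPanel,
    spec: ModelSpec,
    config: InferenceConfig,
    fix_hyper: Hyperparameters | None = None,
    init_hyper: Hyperparameters | None = None,
    likelihood: str = "poisson",
    gaussian_sd: float = 1.0,
) -> PosteriorResult:
    """Adaptive-Metropolis hyperparameter chain with Laplace-marginalized target.

    With ``fix_hyper`` the chain is skipped and latent draws are generated at
    the given hyperparameters (useful for validation and the GLM limit).
    Reproducible bit-for-bit under a fixed seed.
    """
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    model = JointModel(panel, spec, likelihood=likelihood, gaussian_sd=gaussian_sd)
    warnings_list: list[str] = []

    def target(hyper, start):
        lap = _laplace(model, hyper, start=start, max_iter=config.max_newton_iter,
                       gtol=config.grad_tol, stol=config.step_tol)
        nat = spec.hyper_to_vector(hyper)
        lp = lap.log_evidence + spec.hyper_logprior(hyper) + spec.hyper_log_jacobian(nat)
        return lp, lap

    n_hyper = len(spec.hyper_names)
    retained_hyper: list[np.ndarray] = []
    retained_z: list[np.ndarray] = []
    retained_eta: list[np.ndarray] = []
    retained_cond: list[tuple] = []
    refresh_acc = refresh_tot = 0

    cond_cache: dict[int, tuple] = {}

    def cond_of(lap):
        key = id(lap)
        if key not in cond_cache:
            cond_cache.clear()
            cond_cache[key] = _conditional_eta_moments(model, lap)
        return cond_cache[key]

    if fix_hyper is not None or n_hyper == 0:
        hyper = fix_hyper if fix_hyper is not None else Hyperparameters()
        _, lap = target(hyper, None)
        w_cur, psi_cur = lap.w.copy(), None if lap.psi is None else lap.psi.copy()
        for _ in range(config.n_retained):
            w_s, psi_s = _sample_latent(model, lap, rng)
            if config.latent_mcmc:
                w_cur, psi_cur, acc = _refresh_latent(
                    model, lap, w_cur, psi_cur, rng, config.latent_mcmc_steps
                )
                refresh_acc += acc
                refresh_tot += config.latent_mcmc_steps
                w_s, psi_s = w_cur, psi_cur
            retained_hyper.append(spec.hyper_to_vector(hyper))
            retained_z.append(_z_record(model, w_s, psi_s))
            retained_eta.append(model.eta(w_s, psi_s))
            retained_cond.append(cond_of(lap))
        acc_rate = 1.0
    else:
        hyper0 = init_hyper or _default_init(spec)
        theta = spec.hyper_transform(spec.hyper_to_vector(hyper0))
        lp, lap = target(hyper0, None)
        hyper = hyper0

        scale = config.init_scale
        cov = np.eye(n_hyper)
        chol_cov = np.eye(n_hyper)
        history = [theta.copy()]
        n_acc_post = n_post = 0
        n_acc_win = 0
        newton_failures = 0
        w_cur, psi_cur = lap.w.copy(), None if lap.psi is None else lap.psi.copy()

        for it in range(config.iterations):
            prop = theta + scale * (chol_cov @ rng.standard_normal(n_hyper))
            accept = False
            try:
                hyper_p = spec.hyper_from_vector(spec.hyper_untransform(prop))
                lp_p, lap_p = target(hyper_p, (lap.w, lap.psi))
                if np.log(rng.random()) < lp_p - lp:
                    accept = True
            except (NewtonError, np.linalg.LinAlgError, ValueError):
                newton_failures += 1
            if accept:
                theta, lp, lap, hyper = prop, lp_p, lap_p, hyper_p
            in_burn = it < config.burn_in
            if in_burn:
                # Robbins-Monro scale adaptation toward the target rate,
                # with empirical proposal covariance once enough history
                gamma = (it + 1) ** -0.6
                scale *= np.exp(gamma * ((1.0 if accept else 0.0) - config.target_accept))
                history.append(theta.copy())
                if it >= 100 and it % 50 == 0:
                    emp = np.cov(np.array(history[-1000:]).T) + 1e-8 * np.eye(n_hyper)
                    cov = emp
                    chol_cov = cholesky(cov, lower=True)
            else:
                n_post += 1
                n_acc_post += int(accept)
                if (it - config.burn_in) % config.thin == 0:
                    w_s, psi_s = _sample_latent(model, lap, rng)
                    if config.latent_mcmc:
                        w_cur, psi_cur, acc = _refresh_latent(
                            model, lap, w_cur, psi_cur, rng, config.latent_mcmc_steps
                        )
                        refresh_acc += acc
                        refresh_tot += config.latent_mcmc_steps
                        w_s, psi_s = w_cur, psi_cur
                    retained_hyper.append(spec.hyper_to_vector(hyper))
                    retained_z.append(_z_record(model, w_s, psi_s))
                    retained_eta.append(model.eta(w_s, psi_s))
                    retained_cond.append(cond_of(lap))
        acc_rate = n_acc_post / max(1, n_post)
        if not 0.05 <= acc_rate <= 0.95:
            warnings_list.append(
                f"post-adaptation acceptance rate {acc_rate:.3f} outside [0.05, 0.95]"
            )
            warnings.warn(warnings_list[-1], stacklevel=2)
        if newton_failures:
            warnings_list.append(f"{newton_failures} proposals rejected on Newton failure")

    eta_draws = np.array(retained_eta)
    ll_draws = np.array([model.obs.loglik(e)[1] for e in eta_draws])
    z_names = _z_names(model)
    meta = {
        "seed": config.seed,
        "iterations": config.iterations,
        "burn_in": config.burn_in,
        "thin": config.thin,
        "acceptance_rate": acc_rate,
        "latent_refresh_acceptance": (refresh_acc / refresh_tot) if refresh_tot else None,
        "runtime_s": time.time() - t0,
        "warnings": warnings_list,
        "likelihood": likelihood,
    }
    cond = (
        np.array([c[0] for c in retained_cond]),
        np.array([c[1] for c in retained_cond]),
        np.array([c[2] for c in retained_cond]),
    )
    return PosteriorResult(
        spec=spec,
        panel=panel,
        hyper_draws=pd.DataFrame(np.array(retained_hyper), columns=spec.hyper_names),
        z_names=z_names,
        z_draws=np.array(retained_z),
        eta_draws=eta_draws,
        loglik_draws=ll_draws,
        metadata=meta,
        cond_moments=cond,
    )


def _default_init(spec: ModelSpec) -> Hyperparameters:
    kw = {}
    if spec.psi_by_disease:
        kw["tau_psi"] = np.full(spec.D, 4.0)
    else:
        kw["tau_psi"] = 4.0
    return Hyperparameters(
        tau_alpha=4.0, tau_lambda=4.0, rho_lambda=0.5, tau_u=4.0, rho_u=0.5,
        tau_phi=4.0, tau_v=4.0, **kw,
    )


def _z_names(model: JointModel) -> list[str]:
    names = []
    for b in model.spec.dense_blocks:
        names += b.z_names
    if model.has_psi:
        names += model.psi_names
    return names


def _z_record(model: JointModel, w, psi) -> np.ndarray:
    z = model.z_dense_from_w(w)
    if model.has_psi:
        return np.concatenate([z, psi])
    return z
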