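"""Structured additive predictor, Poisson likelihood and joint log-posterior.

The observation model is ``Y_itd ~ Poisson(E_itd * theta_itd)`` with
``log theta`` assembled additively from the latent components.  The joint
log-posterior over (fixed effects, latent field) is concave for fixed
hyperparameters (canonical-link Poisson plus Gaussian priors), which the
inference module exploits with Newton iterations.

A Gaussian observation model with known noise sd is also provided; it is
used for validation (the Laplace approximation is exact there) and is not
part of the epidemiological analysis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import gammaln

from .modelspec import ConstraintViolationError, ModelSpec
from .panel import MortalityPanel
from .priors import Hyperparameters

#: |eta| beyond which exp() would dwarf any realistic mortality ratio;
#: the likelihood is reported as -inf rather than overflowing.
ETA_GUARD = 35.0


@dataclasses.dataclass
class FixedEffects:
    """Covariate coefficients (standardized scale) and disease intercepts."""

    beta: np.ndarray | None = None
    alpha: np.ndarray | None = None


@dataclasses.dataclass
class LatentState:
    """All latent effect vectors, plus the internal BYM2 halves.

    Shapes: ``lam`` (I,), ``u`` (I, D), ``phi`` (T,), ``v`` (T, D),
    ``psi`` (I, T, D).  ``lam_star`` and ``u_star`` are the scaled-ICAR
    structured halves of the BYM2 components (needed to evaluate their
    joint prior; the predictor only uses the combined effects).
    """

    lam: np.ndarray | None = None
    u: np.ndarray | None = None
    phi: np.ndarray | None = None
    v: np.ndarray | None = None
    psi: np.ndarray | None = None
    lam_star: np.ndarray | None = None
    u_star: np.ndarray | None = None


def assemble_predictor(
    fixed: FixedEffects, latent: LatentState, panel: MortalityPanel
) -> np.ndarray:
    """Row-wise linear predictor eta = log(theta) in canonical panel order.

    Absent components (``None`` fields) contribute zero.  Raises IndexError
    naming the offending row if any index is out of range.
    """
    i, t, d = panel.country_idx, panel.year_idx, panel.disease_idx
    eta = np.zeros(panel.n_rows)
    try:
        if fixed.alpha is not None:
            eta += np.asarray(fixed.alpha)[d]
        if fixed.beta is not None:
            eta += panel.covariate_matrix() @ np.asarray(fixed.beta)
        if latent.lam is not None:
            eta += np.asarray(latent.lam)[i]
        if latent.u is not None:
            eta += np.asarray(latent.u)[i, d]
        if latent.phi is not None:
            eta += np.asarray(latent.phi)[t]
        if latent.v is not None:
            eta += np.asarray(latent.v)[t, d]
        if latent.psi is not None:
            eta += np.asarray(latent.psi)[i, t, d]
    except IndexError as exc:
        raise IndexError(f"latent component index out of range for panel rows: {exc}") from exc
    return eta


def poisson_loglik(y, E, eta) -> tuple[float, np.ndarray]:
    """Poisson log-likelihood with offset E; returns (total, per-row).

    per-row = y*(log E + eta) - E*exp(eta) - log Gamma(y+1); rows where
    |eta| exceeds the overflow guard contribute -inf.
    """
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(E <= 0):
        raise ValueError("offset E must be strictly positive")
    ok = np.abs(eta) <= ETA_GUARD
    safe = np.where(ok, eta, 0.0)
    per = np.where(
        ok,
        y * (np.log(E) + safe) - E * np.exp(safe) - gammaln(y + 1.0),
        -np.inf,
    )
    total = float(per.sum()) if ok.all() else -np.inf
    return total, per


def poisson_loglik_grad(y, E, eta) -> np.ndarray:
    """d loglik / d eta = y - E exp(eta), elementwise."""
    return np.asarray(y, float) - np.asarray(E, float) * np.exp(np.asarray(eta, float))


class PoissonObs:
    """Poisson observation model with multiplicative offset."""

    def __init__(self, y, E):
        self.y = np.asarray(y, dtype=float)
        self.E = np.asarray(E, dtype=float)

    def loglik(self, eta):
        return poisson_loglik(self.y, self.E, eta)

    def grad_hess(self, eta):
        mu = self.E * np.exp(np.clip(eta, -ETA_GUARD, ETA_GUARD))
        return self.y - mu, mu  # gradient, negative curvature (both per row)


class GaussianObs:
    """Gaussian observation model with known noise sd (validation only)."""

    def __init__(self, y, sd):
        self.y = np.asarray(y, dtype=float)
        self.sd = float(sd)

    def loglik(self, eta):
        r = (self.y - eta) / self.sd
        per = -0.5 * r**2 - np.log(self.sd) - 0.5 * np.log(2.0 * np.pi)
        return float(per.sum()), per

    def grad_hess(self, eta):
        prec = 1.0 / self.sd**2
        return (self.y - eta) * prec, np.full_like(self.y, prec)


class JointModel:
    """Numerical engine binding a panel to a model specification.

    Internally the dense latent blocks are handled on the orthonormal
    constraint-null-space basis (``z = B w``), so the restricted prior
    precision of every block is positive definite; the iid interaction
    ``psi`` (one cell per panel row) is kept apart as a diagonal block.
    """

    def __init__(self, panel: MortalityPanel, spec: ModelSpec, likelihood: str = "poisson",
                 gaussian_sd: float = 1.0):
        if list(spec.countries) != list(panel.countries):
            raise ValueError("spec graph nodes must match panel countries (same order)")
        if list(spec.diseases) != list(panel.diseases):
            raise ValueError("spec diseases must match panel diseases")
        if spec.T != panel.n_years:
            raise ValueError("spec years must match panel years")
        self.panel = panel
        self.spec = spec
        if likelihood == "poisson":
            self.obs = PoissonObs(panel.y, panel.expected)
        elif likelihood == "gaussian":
            self.obs = GaussianObs(panel.y, gaussian_sd)
        else:
            raise ValueError(f"unknown likelihood {likelihood!r}")
        self.likelihood = likelihood
        self.n = panel.n_rows

        # dense design on the constrained basis: X = [A_block @ B_block ...]
        cols = []
        for b in spec.dense_blocks:
            cols.append(b.design_fn(panel) @ b.B)
        self.X = np.hstack(cols) if cols else np.zeros((self.n, 0))
        self.m_w = self.X.shape[1]
        self.has_psi = spec.has_psi

        self.w_names: list[str] = []
        for b in spec.dense_blocks:
            self.w_names += [f"{b.name}:w{k}" for k in range(b.w_size)]
        d_lab = [spec.diseases[k] for k in panel.disease_idx]
        i_lab = [spec.countries[k] for k in panel.country_idx]
        t_lab = [spec.years[k] for k in panel.year_idx]
        self.psi_names = [f"psi[{d},{i},{t}]" for d, i, t in zip(d_lab, i_lab, t_lab)]

    # -- priors ----------------------------------------------------------
    def psi_precisions(self, hyper: Hyperparameters) -> np.ndarray:
        """Per-row prior precision of psi (scalar tau or per-disease)."""
        tau = np.atleast_1d(np.asarray(hyper.tau_psi, dtype=float))
        if tau.size == 1:
            return np.full(self.n, float(tau[0]))
        if tau.size != self.spec.D:
            raise ValueError("per-disease tau_psi must have one entry per disease")
        return tau[self.panel.disease_idx]

    def Qw_dense(self, hyper: Hyperparameters) -> tuple[np.ndarray, float]:
        """Block-diagonal restricted prior precision of the dense part and its logdet."""
        Q = np.zeros((self.m_w, self.m_w))
        logdet = 0.0
        for b in self.spec.dense_blocks:
            sl = self.spec.w_slices[b.name]
            Qb = b.B.T @ b.Q_fn(hyper) @ b.B
            Q[sl, sl] = Qb
            sign, ld = np.linalg.slogdet(Qb)
            if sign <= 0:
                raise np.linalg.LinAlgError(f"restricted prior precision of {b.name} not PD")
            logdet += ld
        return Q, logdet

    # -- state conversion -------------------------------------------------
    def z_dense_from_w(self, w: np.ndarray) -> np.ndarray:
        z = np.zeros(self.spec.m_z)
        for b in self.spec.dense_blocks:
            z[self.spec.z_slices[b.name]] = b.B @ w[self.spec.w_slices[b.name]]
        return z

    def state_from_w(self, w: np.ndarray, psi_flat: np.ndarray | None) -> tuple[FixedEffects, LatentState]:
        spec = self.spec
        z = self.z_dense_from_w(w)
        fixed = FixedEffects()
        latent = LatentState()
        I, D, T = spec.I, spec.D, spec.T
        for b in spec.dense_blocks:
            zb = z[spec.z_slices[b.name]]
            if b.name == "beta":
                fixed.beta = zb.copy()
            elif b.name == "alpha":
                fixed.alpha = zb.copy()
            elif b.name == "lambda":
                latent.lam = zb[:I].copy()
                latent.lam_star = zb[I:].copy()
            elif b.name.startswith("u:"):
                if latent.u is None:
                    latent.u = np.zeros((I, D))
                    latent.u_star = np.zeros((I, D))
                d_ix = spec.diseases.index(b.name.split(":", 1)[1])
                latent.u[:, d_ix] = zb[:I]
                latent.u_star[:, d_ix] = zb[I:]
            elif b.name == "phi":
                latent.phi = zb.copy()
            elif b.name.startswith("v:"):
                if latent.v is None:
                    latent.v = np.zeros((T, D))
                d_ix = spec.diseases.index(b.name.split(":", 1)[1])
                latent.v[:, d_ix] = zb
        if psi_flat is not None:
            psi = np.zeros((I, T, D))
            psi[self.panel.country_idx, self.panel.year_idx, self.panel.disease_idx] = psi_flat
            latent.psi = psi
        return fixed, latent

    def flat_z(self, fixed: FixedEffects, latent: LatentState) -> tuple[np.ndarray, np.ndarray | None]:
        """Inverse of :meth:`state_from_w` on the z scale (dense z, flat psi)."""
        spec = self.spec
        z = np.zeros(spec.m_z)
        for b in spec.dense_blocks:
            sl = spec.z_slices[b.name]
            if b.name == "beta":
                z[sl] = np.asarray(fixed.beta, dtype=float)
            elif b.name == "alpha":
                z[sl] = np.asarray(fixed.alpha, dtype=float)
            elif b.name == "lambda":
                z[sl] = np.concatenate([latent.lam, latent.lam_star])
            elif b.name.startswith("u:"):
                d_ix = spec.diseases.index(b.name.split(":", 1)[1])
                z[sl] = np.concatenate([latent.u[:, d_ix], latent.u_star[:, d_ix]])
            elif b.name == "phi":
                z[sl] = np.asarray(latent.phi, dtype=float)
            elif b.name.startswith("v:"):
                d_ix = spec.diseases.index(b.name.split(":", 1)[1])
                z[sl] = np.asarray(latent.v[:, d_ix], dtype=float)
        psi_flat = None
        if self.has_psi:
            if latent.psi is None:
                raise ValueError("spec includes psi but latent.psi is None")
            psi_flat = np.asarray(latent.psi, dtype=float)[
                self.panel.country_idx, self.panel.year_idx, self.panel.disease_idx
            ]
        return z, psi_flat

    def eta(self, w: np.ndarray, psi_flat: np.ndarray | None) -> np.ndarray:
        out = self.X @ w if self.m_w else np.zeros(self.n)
        if psi_flat is not None:
            out = out + psi_flat
        return out

    # -- constraint check -------------------------------------------------
    def check_constraints(self, fixed: FixedEffects, latent: LatentState, tol: float = 1e-6):
        z, _ = self.flat_z(fixed, latent)
        for b in self.spec.dense_blocks:
            if b.C is None:
                continue
            viol = np.abs(b.C @ z[self.spec.z_slices[b.name]]).max()
            if viol > tol:
                raise ConstraintViolationError(
                    f"block {b.name}: constraint violation {viol:.3e} exceeds {tol:.1e}"
                )


def log_posterior(
    fixed: FixedEffects,
    latent: LatentState,
    hyper: Hyperparameters,
    panel: MortalityPanel,
    spec: ModelSpec,
    return_blocks: bool = False,
):
    """Joint log-posterior density (up to a constant) with per-block terms.

    Sum of the Poisson log-likelihood, the Gaussian log-priors of every
    latent block evaluated on its constrained subspace (including the
    restricted normalizing constants), and the PC hyperprior log-densities.
    Raises :class:`ConstraintViolationError` rather than silently projecting
    a state that violates its sum-to-zero constraints.
    """
    model = JointModel(panel, spec)
    model.check_constraints(fixed, latent)
    z, psi_flat = model.flat_z(fixed, latent)

    eta = assemble_predictor(fixed, latent, panel)
    ll, _ = poisson_loglik(panel.y, panel.expected, eta)
    blocks = {"likelihood": ll}

    for b in spec.dense_blocks:
        zb = z[spec.z_slices[b.name]]
        Qb = b.B.T @ b.Q_fn(hyper) @ b.B
        wb = b.B.T @ zb  # orthonormal basis: coordinates of zb in the subspace
        sign, ld = np.linalg.slogdet(Qb)
        val = -0.5 * wb @ Qb @ wb + 0.5 * ld - 0.5 * b.w_size * np.log(2.0 * np.pi)
        key = b.component
        blocks[key] = blocks.get(key, 0.0) + float(val)
    if spec.has_psi:
        d = model.psi_precisions(hyper)
        blocks["psi"] = float(
            -0.5 * np.sum(d * psi_flat**2) + 0.5 * np.sum(np.log(d)) - 0.5 * model.n * np.log(2.0 * np.pi)
        )
    blocks["hyperprior"] = spec.hyper_logprior(hyper)
    total = float(sum(blocks.values()))
    return (total, blocks) if return_blocks else total


def log_posterior_grad(
    fixed: FixedEffects,
    latent: LatentState,
    hyper: Hyperparameters,
    panel: MortalityPanel,
    spec: ModelSpec,
) -> np.ndarray:
    """Gradient of :func:`log_posterior` wrt the flat (dense z, psi) vector.

    Order: the dense blocks in spec order on their natural (z) coordinates,
    followed by psi in canonical row order.  For constrained blocks the
    gradient is projected onto the constraint subspace (the directions in
    which the state may move).
    """
    model = JointModel(panel, spec)
    model.check_constraints(fixed, latent)
    z, psi_flat = model.flat_z(fixed, latent)
    eta = assemble_predictor(fixed, latent, panel)
    g_eta = poisson_loglik_grad(panel.y, panel.expected, eta)

    grad = np.zeros(spec.m_z + (model.n if spec.has_psi else 0))
    for b in spec.dense_blocks:
        sl = spec.z_slices[b.name]
        A = b.design_fn(panel)
        gb = A.T @ g_eta - b.Q_fn(hyper) @ z[sl]
        P = b.B @ b.B.T  # projector onto the constraint null space
        grad[sl] = P @ gb
    if spec.has_psi:
        d = model.psi_precisions(hyper)
        grad[spec.m_z :] = g_eta - d * psi_flat
    return grad
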