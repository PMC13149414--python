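"""Penalized-complexity hyperpriors and the BYM2 spatial specification.

Every latent component carries a single precision ``tau`` with a PC prior
(exponential on the distance-from-base scale, i.e. exponential on the
standard deviation ``sigma = tau**-0.5``), calibrated by a tail statement
``P(sigma > U) = alpha``.  BYM2 components additionally carry a mixing
parameter ``rho`` in [0, 1] that interpolates between pure iid noise
(``rho = 0``) and the pure scaled ICAR field (``rho = 1``); its PC prior is
built numerically from the Kullback-Leibler distance between the BYM2 model
at ``rho`` and the iid base model.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.linalg import cholesky, null_space, solve_triangular
from scipy.optimize import brentq

from .structures import StructureMatrix


@dataclasses.dataclass(frozen=True)
class PCPrecisionPrior:
    """PC prior on a precision: sigma = tau**-0.5 ~ Exponential(rate).

    ``rate = -log(alpha) / U`` so that ``P(sigma > U) = alpha``.  On the
    precision scale the density is
    ``p(tau) = (rate / 2) * tau**-1.5 * exp(-rate * tau**-0.5)``.
    """

    U: float = 1.0
    alpha: float = 0.01

    def __post_init__(self):
        if not (self.U > 0 and 0 < self.alpha < 1):
            raise ValueError("require U > 0 and alpha in (0, 1)")

    @property
    def rate(self) -> float:
        return -math.log(self.alpha) / self.U

    def logpdf(self, tau):
        tau = np.asarray(tau, dtype=float)
        if np.any(tau <= 0):
            raise ValueError("precision must be positive")
        lam = self.rate
        return np.log(lam / 2.0) - 1.5 * np.log(tau) - lam / np.sqrt(tau)

    def sigma_tail_prob(self, s) -> np.ndarray:
        """P(sigma > s) under the prior (exponential survival)."""
        return np.exp(-self.rate * np.asarray(s, dtype=float))

    def sample_sigma(self, rng: np.random.Generator, size=None):
        return rng.exponential(1.0 / self.rate, size=size)


class PCMixingPrior:
    """PC prior for the BYM2 mixing parameter ``rho``.

    The distance from the iid base model is
    ``d(rho) = sqrt(sum_i g(1 - rho + rho * gamma_i))`` with
    ``g(e) = e - 1 - log(e)`` and ``gamma_i`` the marginal-variance
    eigenvalues of the scaled structure (inverses of the non-null
    eigenvalues of ``Q*``).  The prior is exponential in ``d`` with rate
    ``theta`` chosen so that ``P(rho < U) = alpha``; because ``d`` is
    monotone, the CDF is available in closed form given ``theta``.
    """

    def __init__(self, structure: StructureMatrix, U: float = 0.5, alpha: float = 2.0 / 3.0):
        if not structure.scaled:
            raise ValueError("PC mixing prior requires a variance-scaled structure")
        if not (0 < U < 1 and 0 < alpha < 1):
            raise ValueError("require U in (0,1) and alpha in (0,1)")
        self.U = float(U)
        self.alpha = float(alpha)
        self.gamma = 1.0 / structure.nonnull_eigenvalues()
        self.d1 = float(self.distance(1.0 - 1e-12))
        self.theta = self._calibrate()

    # -- distance ---------------------------------------------------------
    def distance(self, rho):
        """KLD-based distance d(rho) from the base model rho = 0."""
        rho = np.asarray(rho, dtype=float)
        e_minus_1 = np.multiply.outer(rho, self.gamma - 1.0)
        g = e_minus_1 - np.log1p(e_minus_1)
        return np.sqrt(np.sum(g, axis=-1))

    def _ddistance(self, rho):
        rho = np.asarray(rho, dtype=float)
        e = 1.0 + np.multiply.outer(rho, self.gamma - 1.0)
        gprime = (1.0 - 1.0 / e) * (self.gamma - 1.0)
        G = np.sum(e - 1.0 - np.log(e), axis=-1)
        Gp = np.sum(gprime, axis=-1)
        d = np.sqrt(G)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(d > 0, Gp / (2.0 * np.where(d > 0, d, 1.0)), 0.0)
        # limit rho -> 0: d ~ rho * sqrt(sum (gamma-1)^2 / 2)
        limit = math.sqrt(float(np.sum((self.gamma - 1.0) ** 2)) / 2.0)
        return np.where(d > 1e-12, out, limit)

    # -- calibration ------------------------------------------------------
    def _cdf_given_theta(self, rho, theta):
        d = self.distance(rho)
        if abs(theta) < 1e-10:
            return d / self.d1
        return -np.expm1(-theta * d) / -math.expm1(-theta * self.d1)

    def _calibrate(self) -> float:
        target = self.alpha

        def f(theta):
            return float(self._cdf_given_theta(self.U, theta)) - target

        lo, hi = -200.0, 200.0
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:  # pragma: no cover - extreme calibrations
            raise ValueError("cannot calibrate PC mixing prior for given (U, alpha)")
        return float(brentq(f, lo, hi, xtol=1e-12))

    # -- densities --------------------------------------------------------
    def cdf(self, rho):
        return self._cdf_given_theta(np.asarray(rho, dtype=float), self.theta)

    def logpdf(self, rho):
        rho = np.asarray(rho, dtype=float)
        if np.any((rho <= 0) | (rho >= 1)):
            raise ValueError("rho must lie strictly inside (0, 1)")
        th = self.theta
        d = self.distance(rho)
        dp = self._ddistance(rho)
        if abs(th) < 1e-10:
            return np.log(dp / self.d1)
        norm = -math.expm1(-th * self.d1)
        return math.log(abs(th)) - th * d + np.log(dp) - math.log(abs(norm))


def bym2_combine(rho, tau, u_star, v_iid):
    """Combine scaled-ICAR and iid halves into the BYM2 effect.

    ``b = (1/sqrt(tau)) * (sqrt(rho) * u_star + sqrt(1-rho) * v_iid)``;
    because ``u_star`` has generalized marginal variance 1 and ``v_iid`` is
    standard normal, the marginal generalized variance of ``b`` is ``1/tau``
    for every ``rho``.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    if not tau > 0:
        raise ValueError("tau must be positive")
    u_star = np.asarray(u_star, dtype=float)
    v_iid = np.asarray(v_iid, dtype=float)
    if u_star.shape != v_iid.shape:
        raise ValueError("structured and iid halves must have equal shape")
    return (math.sqrt(rho) * u_star + math.sqrt(1.0 - rho) * v_iid) / math.sqrt(tau)


def bym2_joint_precision(rho: float, tau: float, Qstar: np.ndarray) -> np.ndarray:
    """Joint precision of ``(b, u_star)`` under the BYM2 model.

    Derived from ``b | u* ~ N(sqrt(rho/tau) u*, (1-rho)/tau I)`` with
    ``u* ~ N(0, Qstar^-)``; positive definite on the subspace where both
    halves satisfy their sum-to-zero constraints.  Requires ``rho`` strictly
    inside (0, 1) to avoid the degenerate boundaries.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError("joint BYM2 precision requires rho strictly in (0, 1)")
    if not tau > 0:
        raise ValueError("tau must be positive")
    n = Qstar.shape[0]
    I = np.eye(n)
    a = tau / (1.0 - rho)
    c = math.sqrt(rho * tau) / (1.0 - rho)
    top = np.hstack([a * I, -c * I])
    bot = np.hstack([-c * I, Qstar + (rho / (1.0 - rho)) * I])
    return np.vstack([top, bot])


def constraint_null_basis(C: np.ndarray, n: int) -> np.ndarray:
    """Orthonormal basis of {x : C x = 0} (identity when no constraints)."""
    if C is None or C.size == 0:
        return np.eye(n)
    return null_space(np.atleast_2d(np.asarray(C, dtype=float)))


def sample_constrained_gaussian(
    Q: np.ndarray,
    C: np.ndarray | None,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw from a (possibly intrinsic) Gaussian with precision Q subject to Cx = 0.

    Implemented by reparameterizing onto an orthonormal basis of the
    constraint null space, where the restricted precision is positive
    definite; equivalent to conditioning the unconstrained field on the
    constraints (conditioning by kriging) for centered Gaussians.
    """
    n = Q.shape[0]
    B = constraint_null_basis(C, n)
    Qw = B.T @ Q @ B
    L = cholesky(Qw, lower=False)  # upper: Qw = L'.T @ L'
    z = rng.standard_normal((size, B.shape[1]))
    w = solve_triangular(L, z.T, lower=False).T
    draws = w @ B.T
    return draws[0] if size == 1 else draws


@dataclasses.dataclass
class Hyperparameters:
    """Precisions and BYM2 mixing parameters of the latent components."""

    tau_alpha: float = 1.0
    tau_lambda: float = 1.0
    rho_lambda: float = 0.5
    tau_u: float = 1.0
    rho_u: float = 0.5
    tau_phi: float = 1.0
    tau_v: float = 1.0
    tau_psi: float = 1.0

    def __post_init__(self):
        for name in ("tau_alpha", "tau_lambda", "tau_u", "tau_phi", "tau_v"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        # tau_psi may be a scalar or a per-disease array
        if not np.all(np.asarray(self.tau_psi) > 0):
            raise ValueError("tau_psi must be positive")
        for name in ("rho_lambda", "rho_u"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d) -> "Hyperparameters":
        return cls(**{k: float(v) for k, v in d.items()})
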