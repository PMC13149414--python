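"""Bayesian model-adequacy diagnostics: DIC, WAIC, CPO/LCPO, PIT, fit tables.

All quantities are computed from the matrix of per-row, per-draw
log-likelihood contributions retained by the sampler, so they can be
recomputed independently from the same matrix (and are, in the test suite).

The conditional predictive ordinate (CPO) of a row is its leave-one-out
predictive density, estimated by the harmonic-mean identity
``CPO_r = 1 / mean_s(1 / L_rs)``; rows where the harmonic estimator is
numerically unstable (one draw dominating the weights, or a zero
likelihood) are counted as CPO failures rather than silently dropped.
PIT values are the leave-one-out probability integral transform for counts
(mid-PIT, importance-weighted by the same CPO weights), which is the
calibration check that should look uniform when the model is adequate.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp


class DiagnosticsError(RuntimeError):
    pass


@dataclasses.dataclass
class DiagnosticsReport:
    dic: float
    p_d: float
    mean_deviance: float
    waic: float
    p_waic: float
    lppd: float
    lcpo: float            # sum of log CPO (harmonic-mean estimator)
    lcpo_mean: float       # mean of log CPO (conventions differ; both emitted)
    cpo: np.ndarray
    cpo_failures: int
    cpo_loo: np.ndarray | None  # Gaussian-subtraction leave-one-out CPO
    lcpo_loo: float
    loo_clamped: int
    pit: np.ndarray
    fitted: pd.DataFrame
    coverage_95: float

    def scalar_table(self) -> pd.DataFrame:
        rows = [
            ("dic", self.dic),
            ("p_d", self.p_d),
            ("mean_deviance", self.mean_deviance),
            ("waic", self.waic),
            ("p_waic", self.p_waic),
            ("lppd", self.lppd),
            ("lcpo_sum", self.lcpo),
            ("lcpo_mean", self.lcpo_mean),
            ("lcpo_loo", self.lcpo_loo),
            ("cpo_failures", float(self.cpo_failures)),
            ("loo_clamped", float(self.loo_clamped)),
            ("pit_ks_statistic", float(stats.kstest(self.pit, "uniform").statistic)),
            ("coverage_95", self.coverage_95),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def to_csv(self, scalar_path, per_row_path):
        self.scalar_table().to_csv(scalar_path, index=False)
        per = self.fitted.copy()
        per["cpo"] = self.cpo
        per["pit"] = self.pit
        per.to_csv(per_row_path, index=False)


def compute_dic(deviances, deviance_at_mean) -> tuple[float, float]:
    """Deviance information criterion from per-draw deviances.

    ``p_D`` is mean deviance minus the deviance at the posterior mean of the
    linear predictor; ``DIC = mean deviance + p_D``.
    """
    deviances = np.asarray(deviances, dtype=float)
    if deviances.size < 100:
        raise ValueError("need at least 100 draws for DIC")
    if not np.all(np.isfinite(deviances)) or not np.isfinite(deviance_at_mean):
        raise DiagnosticsError("non-finite deviances")
    dbar = float(deviances.mean())
    p_d = dbar - float(deviance_at_mean)
    return dbar + p_d, p_d


def compute_waic(loglik: np.ndarray) -> tuple[float, float, float]:
    """WAIC from the (draws x rows) log-likelihood matrix.

    ``lppd = sum_r log mean_s exp(ll_rs)`` (log-sum-exp),
    ``p_WAIC = sum_r var_s(ll_rs)``, ``WAIC = -2 (lppd - p_WAIC)``.
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("expect a (draws, rows) matrix")
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    if S == 1:
        p_waic = 0.0
    else:
        p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
        if S > 10_000 and np.any(ll.var(axis=0, ddof=1) == 0.0):
            warnings.warn("rows with zero log-likelihood variance across draws", stacklevel=2)
    return -2.0 * (lppd - p_waic), p_waic, lppd


def compute_cpo(loglik: np.ndarray, weight_threshold: float = 0.95):
    """Harmonic-mean CPO per row, LCPO, and failure count.

    Operates on log-likelihoods for stability:
    ``log CPO_r = log S - logsumexp_s(-ll_rs)``.  A row fails when the
    largest importance weight ``w_s ∝ exp(-ll_rs)`` exceeds the
    concentration threshold or the estimate is non-finite.
    """
    ll = np.asarray(loglik, dtype=float)
    S = ll.shape[0]
    neg = -ll
    lse = logsumexp(neg, axis=0)
    log_cpo = np.log(S) - lse
    wmax = np.exp(neg.max(axis=0) - lse)
    failures = (~np.isfinite(log_cpo)) | (wmax > weight_threshold)
    cpo = np.exp(log_cpo)
    lcpo = float(np.sum(log_cpo))
    return cpo, lcpo, int(failures.sum())


def loo_weights(loglik: np.ndarray) -> np.ndarray:
    """Normalized leave-one-out importance weights per (draw, row)."""
    neg = -np.asarray(loglik, dtype=float)
    return np.exp(neg - logsumexp(neg, axis=0, keepdims=True))


def compute_pit(mu_draws: np.ndarray, y, loglik: np.ndarray | None = None,
                weighting: str = "loo") -> np.ndarray:
    """Mid-PIT per observation from posterior draws of the Poisson mean.

    ``PIT_r = P(Y_rep < y_r) + 0.5 P(Y_rep = y_r)`` under the predictive
    distribution, averaged over draws of ``mu = E * theta``.  With
    ``weighting="loo"`` (default) the draws are importance-weighted by the
    CPO weights so the predictive is leave-one-out, matching the convention
    of deriving PIT from the CPO machinery; ``weighting="posterior"`` gives
    the plain in-sample posterior-predictive PIT.
    """
    mu = np.asarray(mu_draws, dtype=float)
    y = np.asarray(y, dtype=float)
    if mu.size == 0 or mu.shape[0] == 0:
        raise ValueError("empty predictive sample")
    if weighting == "loo":
        if loglik is None:
            raise ValueError("loo weighting needs the log-likelihood matrix")
        w = loo_weights(loglik)
    elif weighting == "posterior":
        w = np.full(mu.shape, 1.0 / mu.shape[0])
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    cdf_below = stats.poisson.cdf(y[None, :] - 1.0, mu)
    pmf_at = stats.poisson.pmf(y[None, :], mu)
    pit = np.sum(w * (cdf_below + 0.5 * pmf_at), axis=0)
    return np.clip(pit, 0.0, 1.0)


def loo_predictive(eta_mode, eta_var, curvature, y, E, n_nodes: int = 31):
    """Leave-one-out predictive checks by Gaussian likelihood subtraction.

    For each retained hyperparameter draw the sampler stores the Gaussian
    conditional marginal of every row's linear predictor, ``N(m_i, v_i)``,
    and the likelihood curvature ``W_i`` at the mode.  Removing row i's own
    (linearized) likelihood gives the leave-one-out Gaussian
    ``precision 1/v_i - W_i`` (positive by construction for fixed
    hyperparameters), against which the Poisson pmf and mid-CDF are
    integrated by Gauss-Hermite quadrature and averaged over draws.  This is
    the stable leave-one-out route when per-cell effects adapt strongly to
    their own observation, where harmonic-mean importance weights collapse.

    Returns (pit, cpo, n_clamped) with ``n_clamped`` the number of
    (draw, row) subtractions clamped for numerical non-positivity.
    """
    m = np.asarray(eta_mode, dtype=float)
    v = np.asarray(eta_var, dtype=float)
    W = np.asarray(curvature, dtype=float)
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    prec_loo = 1.0 / v - W
    n_clamped = int(np.sum(prec_loo <= 0))
    prec_loo = np.maximum(prec_loo, 1e-10)
    # working observation of the linearized likelihood at the mode
    work = m + (y[None, :] - E[None, :] * np.exp(np.clip(m, -35, 35))) / W
    m_loo = (m / v - W * work) / prec_loo
    s_loo = 1.0 / np.sqrt(prec_loo)
    nodes, wts = np.polynomial.hermite_e.hermegauss(n_nodes)
    wts = wts / wts.sum()
    pit = np.zeros(m.shape[1])
    cpo = np.zeros(m.shape[1])
    S = m.shape[0]
    for k, (x, wk) in enumerate(zip(nodes, wts)):
        eta = np.clip(m_loo + s_loo * x, -35.0, 35.0)
        mu = E[None, :] * np.exp(eta)
        pit += wk * (stats.poisson.cdf(y[None, :] - 1.0, mu)
                     + 0.5 * stats.poisson.pmf(y[None, :], mu)).sum(axis=0)
        cpo += wk * stats.poisson.pmf(y[None, :], mu).sum(axis=0)
    return np.clip(pit / S, 0.0, 1.0), cpo / S, n_clamped


def observed_vs_fitted(panel, posterior, rng: np.random.Generator | None = None) -> tuple[pd.DataFrame, float]:
    """Observed vs fitted table and a leave-one-out 95% coverage statistic.

    The table reports, per row, the posterior mean of ``E * theta`` and a
    95% posterior-predictive interval (from sampled replicate counts).  The
    coverage statistic is the fraction of leave-one-out PIT values inside
    [0.025, 0.975], which estimates the coverage of central 95% predictive
    intervals without the optimism of in-sample intervals.
    """
    if rng is None:
        rng = np.random.default_rng(posterior.metadata.get("seed", 0) + 2_000_003)
    mu = posterior.mu_draws
    y_rep = rng.poisson(mu)
    lo, hi = np.percentile(y_rep, [2.5, 97.5], axis=0)
    fitted = pd.DataFrame(
        {
            "country_id": panel.df["country_id"],
            "year": panel.df["year"],
            "disease": panel.df["disease"],
            "observed": panel.y,
            "fitted_mean": mu.mean(axis=0),
            "pred_lo2.5": lo,
            "pred_hi97.5": hi,
        }
    )
    if posterior.cond_moments is not None:
        pit, _, _ = loo_predictive(*posterior.cond_moments, panel.y, panel.expected)
    else:
        pit = compute_pit(mu, panel.y, posterior.loglik_draws, weighting="loo")
    coverage = float(np.mean((pit >= 0.025) & (pit <= 0.975)))
    return fitted, coverage


def run_diagnostics(panel, posterior) -> DiagnosticsReport:
    """Full adequacy suite for a fitted model."""
    ll = posterior.loglik_draws
    deviances = -2.0 * ll.sum(axis=1)
    eta_mean = posterior.eta_draws.mean(axis=0)
    from .model import poisson_loglik

    dev_at_mean = -2.0 * poisson_loglik(panel.y, panel.expected, eta_mean)[0]
    dic, p_d = compute_dic(deviances, dev_at_mean)
    waic, p_waic, lppd = compute_waic(ll)
    cpo, lcpo, failures = compute_cpo(ll)
    if posterior.cond_moments is not None:
        pit, cpo_g, clamped = loo_predictive(
            *posterior.cond_moments, panel.y, panel.expected
        )
        lcpo_loo = float(np.sum(np.log(np.maximum(cpo_g, 1e-300))))
    else:
        pit = compute_pit(posterior.mu_draws, panel.y, ll, weighting="loo")
        cpo_g, lcpo_loo, clamped = None, float("nan"), 0
    fitted, coverage = observed_vs_fitted(panel, posterior)
    if lcpo > lppd + 1e-8:
        raise DiagnosticsError("LCPO exceeded lppd: harmonic-mean identity violated")
    return DiagnosticsReport(
        dic=dic,
        p_d=p_d,
        mean_deviance=float(deviances.mean()),
        waic=waic,
        p_waic=p_waic,
        lppd=lppd,
        lcpo=lcpo,
        lcpo_mean=lcpo / ll.shape[1],
        cpo=cpo,
        cpo_failures=failures,
        cpo_loo=cpo_g,
        lcpo_loo=lcpo_loo,
        loo_clamped=clamped,
        pit=pit,
        fitted=fitted,
        coverage_95=coverage,
    )
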