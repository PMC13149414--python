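"""Seeded synthetic mortality panels with the model's own statistical structure.

The generator emulates the study design the analysis targets: a balanced
panel of seven EAC countries x four NCD groups x twenty years (2000-2019),
an areal adjacency graph, eight temporally and spatially autocorrelated
covariates, latent effects drawn from the model's constrained priors at
known hyperparameters, and Poisson death counts against expected deaths
derived from populations and baseline age-standardized rates.  Every draw
is reproducible from the seed, and the generating ground truth is returned
alongside the panel so recovery and calibration can be tested end to end.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .graphs import CountryGraph, build_eac_graph, random_connected_graph
from .model import FixedEffects, JointModel, LatentState
from .modelspec import ModelSpec
from .panel import COVARIATES, MortalityPanel, compute_expected_deaths, standardize_covariates, validate_panel
from .priors import Hyperparameters

DISEASES = ["cardiovascular", "diabetes", "neoplasms", "respiratory"]

#: baseline age-standardized mortality rates per 100,000 (orders of magnitude
#: typical of national NCD series)
BASELINE_RATES = {
    "cardiovascular": 250.0,
    "diabetes": 40.0,
    "neoplasms": 120.0,
    "respiratory": 80.0,
}

#: emission scale (location, spread) per covariate, loosely matching the
#: units of the real-world sources (index, deg C, mm, USD, USD, %, /km2, ug/m3)
COVARIATE_SCALES = {
    "ndvi": (0.5, 0.15),
    "temperature": (22.0, 4.0),
    "precipitation": (1100.0, 300.0),
    "gdp_pc": (1500.0, 700.0),
    "health_exp": (80.0, 35.0),
    "urbanization": (30.0, 10.0),
    "pop_density": (120.0, 60.0),
    "pm25": (35.0, 10.0),
}

#: generating coefficients on the standardized-covariate scale
TRUE_BETA = {
    "ndvi": -0.05,
    "temperature": 0.08,
    "precipitation": -0.03,
    "gdp_pc": -0.12,
    "health_exp": -0.10,
    "urbanization": 0.10,
    "pop_density": 0.04,
    "pm25": 0.12,
}


def default_true_hyper() -> Hyperparameters:
    """Generating hyperparameters: moderate effect scales typical of
    national-level disease mapping (sd on the log-risk scale)."""
    s = {"alpha": 0.4, "lambda": 0.3, "u": 0.2, "phi": 0.25, "v": 0.15, "psi": 0.1}
    return Hyperparameters(
        tau_alpha=1.0 / s["alpha"] ** 2,
        tau_lambda=1.0 / s["lambda"] ** 2,
        rho_lambda=0.6,
        tau_u=1.0 / s["u"] ** 2,
        rho_u=0.5,
        tau_phi=1.0 / s["phi"] ** 2,
        tau_v=1.0 / s["v"] ** 2,
        tau_psi=1.0 / s["psi"] ** 2,
    )


@dataclasses.dataclass
class SimulationConfig:
    """Generator settings; defaults reproduce the 7 x 4 x 20 study design."""

    seed: int
    n_countries: int = 7
    n_years: int = 20
    first_year: int = 2000
    diseases: tuple = tuple(DISEASES)
    graph: str | CountryGraph = "eac"
    include_lake_borders: bool = False
    true_beta: dict = dataclasses.field(default_factory=lambda: dict(TRUE_BETA))
    true_hyper: Hyperparameters = dataclasses.field(default_factory=default_true_hyper)
    ar_coefficient: float = 0.7
    ar_sd: float = 0.5
    spatial_smoothing: float = 0.5
    population_range: tuple = (1e6, 1e8)
    population_growth: float = 0.015
    baseline_rates: dict = dataclasses.field(default_factory=lambda: dict(BASELINE_RATES))
    rate_country_sd: float = 0.15
    exposure_multiplier: float = 1.0

    def __post_init__(self):
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("AR coefficient must lie strictly inside (-1, 1)")

    @property
    def years(self) -> list[int]:
        return list(range(self.first_year, self.first_year + self.n_years))

    def build_graph(self, rng: np.random.Generator) -> CountryGraph:
        if isinstance(self.graph, CountryGraph):
            return self.graph
        if self.graph == "eac":
            if self.n_countries != 7:
                raise ValueError("the EAC graph has exactly 7 countries")
            return build_eac_graph(self.include_lake_borders)
        if self.graph == "random":
            return random_connected_graph(self.n_countries, rng)
        raise ValueError(f"unknown graph choice {self.graph!r}")


@dataclasses.dataclass
class GroundTruth:
    """Everything used to generate a panel (sufficient to recompute eta)."""

    fixed: FixedEffects
    latent: LatentState
    hyper: Hyperparameters
    eta: np.ndarray

    def to_csv(self, path, spec: ModelSpec):
        rows = []
        for name, vec in [("beta", self.fixed.beta), ("alpha", self.fixed.alpha)]:
            labels = spec.covariates if name == "beta" else spec.diseases
            for lab, v in zip(labels, vec):
                rows.append({"parameter": f"{name}[{lab}]", "value": v})
        for c, v in zip(spec.countries, self.latent.lam):
            rows.append({"parameter": f"lambda[{c}]", "value": v})
        for d_ix, d in enumerate(spec.diseases):
            for c_ix, c in enumerate(spec.countries):
                rows.append({"parameter": f"u[{d},{c}]", "value": self.latent.u[c_ix, d_ix]})
        for yv, v in zip(spec.years, self.latent.phi):
            rows.append({"parameter": f"phi[{yv}]", "value": v})
        for d_ix, d in enumerate(spec.diseases):
            for t_ix, yv in enumerate(spec.years):
                rows.append({"parameter": f"v[{d},{yv}]", "value": self.latent.v[t_ix, d_ix]})
        for d_ix, d in enumerate(spec.diseases):
            for c_ix, c in enumerate(spec.countries):
                for t_ix, yv in enumerate(spec.years):
                    rows.append(
                        {
                            "parameter": f"psi[{d},{c},{yv}]",
                            "value": self.latent.psi[c_ix, t_ix, d_ix],
                        }
                    )
        for k, v in self.hyper.as_dict().items():
            rows.append({"parameter": k, "value": float(np.atleast_1d(v)[0])})
        pd.DataFrame(rows).to_csv(path, index=False)


def simulate_covariates(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Country-year covariate table: AR(1) in time around graph-smoothed means.

    Each covariate is a stationary AR(1) deviation (coefficient from the
    config, stationary sd ``ar_sd``) around a country-level mean whose
    neighbor correlation comes from one-step graph smoothing; values are
    emitted on realistic unstandardized scales.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    graph = config.build_graph(rng)
    I, T = graph.n_nodes, config.n_years
    W = graph.adjacency()
    deg = W.sum(axis=1)
    a = config.ar_coefficient
    w = config.spatial_smoothing
    out = {"country_id": np.repeat(graph.nodes, T), "year": np.tile(config.years, I)}
    for cov in COVARIATES:
        m = rng.standard_normal(I)
        with np.errstate(invalid="ignore", divide="ignore"):
            nbr_mean = np.where(deg > 0, (W @ m) / np.where(deg > 0, deg, 1.0), m)
        m = (1.0 - w) * m + w * nbr_mean
        z = np.empty((I, T))
        z[:, 0] = rng.standard_normal(I) * config.ar_sd
        innov_sd = config.ar_sd * math.sqrt(1.0 - a**2)
        for t in range(1, T):
            z[:, t] = a * z[:, t - 1] + rng.standard_normal(I) * innov_sd
        loc, scale = COVARIATE_SCALES[cov]
        out[cov] = (loc + scale * (m[:, None] + z)).ravel()
    return pd.DataFrame(out)


def simulate_panel(config: SimulationConfig) -> tuple[MortalityPanel, GroundTruth]:
    """Generate a balanced panel and its ground truth from the model priors.

    Populations and per-disease baseline rates set the expected deaths;
    latent components are drawn from their constrained (scaled) priors at
    the configured true hyperparameters; counts are Poisson with mean
    ``E * exp(eta)``.
    """
    rng = np.random.default_rng(config.seed)
    graph = config.build_graph(rng)
    covs = simulate_covariates(config, rng)

    I, T = graph.n_nodes, config.n_years
    diseases = sorted(config.diseases)
    lo, hi = config.population_range
    pop0 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=I)) * config.exposure_multiplier
    growth = (1.0 + config.population_growth) ** np.arange(T)
    pop = pop0[:, None] * growth[None, :]

    base = np.array([config.baseline_rates[d] for d in diseases])
    country_factor = np.exp(rng.normal(0.0, config.rate_country_sd, size=(I, len(diseases))))
    asmr = base[None, :] * country_factor  # (I, D), constant over years

    rows = []
    for d_ix, d in enumerate(diseases):
        for i_ix, c in enumerate(graph.nodes):
            for t_ix, yv in enumerate(config.years):
                rows.append(
                    {
                        "country_id": c,
                        "year": yv,
                        "disease": d,
                        "deaths": 0,
                        "population": pop[i_ix, t_ix],
                        "asmr": asmr[i_ix, d_ix],
                    }
                )
    df = pd.DataFrame(rows).merge(covs, on=["country_id", "year"], how="left")
    df["expected_deaths"] = compute_expected_deaths(df["population"], df["asmr"])
    panel = validate_panel(df, covariates=COVARIATES)

    spec = ModelSpec(graph, diseases, config.years, COVARIATES)
    panel_std, _ = standardize_covariates(panel)
    model = JointModel(panel_std, spec)
    hyper = config.true_hyper

    # latent draws from the constrained priors (zero when a precision is inf)
    w = np.zeros(spec.m_w)
    for b in spec.dense_blocks:
        sl = spec.w_slices[b.name]
        if b.name == "beta":
            w[sl] = np.array([config.true_beta[c] for c in COVARIATES])
            continue
        tau = {
            "alpha": hyper.tau_alpha,
            "lambda": hyper.tau_lambda,
            "u": hyper.tau_u,
            "phi": hyper.tau_phi,
            "v": hyper.tau_v,
        }[b.component]
        if not np.isfinite(tau):
            continue
        Qb = b.B.T @ b.Q_fn(hyper) @ b.B
        L = np.linalg.cholesky(np.linalg.inv(Qb))
        w[sl] = L @ rng.standard_normal(b.w_size)
    tau_psi = model.psi_precisions(hyper)
    psi = np.where(np.isfinite(tau_psi), rng.standard_normal(model.n) / np.sqrt(tau_psi), 0.0)

    eta = model.eta(w, psi)
    mu = panel.expected * np.exp(eta)
    if np.max(mu) > 1e15:
        raise OverflowError(
            "Poisson mean overflow: reduce population_range / exposure_multiplier "
            f"(max mean {np.max(mu):.3e})"
        )
    y = rng.poisson(mu)

    out_df = panel.df.copy()
    out_df["deaths"] = y.astype(int)
    final_panel = validate_panel(out_df, covariates=COVARIATES)

    fixed, latent = model.state_from_w(w, psi)
    truth = GroundTruth(fixed=fixed, latent=latent, hyper=hyper, eta=eta)
    return final_panel, truth
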