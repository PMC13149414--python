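"""Latent component specification for the joint shared-component model.

The structured additive predictor of the relative risk is

    log(theta_itd) = alpha_d + x_it' beta + lambda_i + u_id
                     + phi_t + v_td + psi_itd

with seven latent pieces: iid disease intercepts ``alpha``, fixed effects
``beta``, a shared BYM2 spatial field ``lambda``, disease-specific BYM2
fields ``u``, a shared RW1 temporal trend ``phi``, disease-specific RW1
trends ``v``, and an iid space-time interaction ``psi`` grouped by disease.
:class:`ModelSpec` assembles, for each active component, its (scaled)
precision structure, its penalized-complexity hyperpriors, its sum-to-zero
identifiability constraints and the orthonormal constraint-null-space basis
used throughout inference.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import yaml

from .graphs import CountryGraph, build_eac_graph
from .priors import (
    Hyperparameters,
    PCMixingPrior,
    PCPrecisionPrior,
    bym2_joint_precision,
    constraint_null_basis,
)
from .structures import StructureMatrix, icar_structure, rw1_structure, scale_structure

ALL_COMPONENTS = ("alpha", "beta", "lambda", "u", "phi", "v", "psi")

DEFAULT_PRECISION_PRIOR = {"U": 1.0, "alpha": 0.01}
DEFAULT_MIXING_PRIOR = {"U": 0.5, "alpha": 2.0 / 3.0}


class ConstraintViolationError(ValueError):
    """A latent state violates its identifiability constraints."""


@dataclasses.dataclass
class DenseBlock:
    """One dense latent block in the internal state vector.

    ``B`` maps the constrained subspace coordinates ``w`` onto the block's
    natural coordinates ``z = B w``; ``C`` holds the constraint rows
    (``C z = 0``).  ``design`` gives the n_rows x size matrix mapping ``z``
    into the linear predictor.
    """

    name: str
    component: str
    size: int
    C: np.ndarray | None
    B: np.ndarray
    Q_fn: Callable[[Hyperparameters], np.ndarray]
    design_fn: Callable[[object], np.ndarray]
    z_names: list[str]

    @property
    def w_size(self) -> int:
        return self.B.shape[1]


class ModelSpec:
    """Definitions, priors and constraints of all latent components."""

    def __init__(
        self,
        graph: CountryGraph | None,
        diseases: Sequence[str],
        years: Sequence[int],
        covariates: Sequence[str],
        components: Sequence[str] = ALL_COMPONENTS,
        priors: dict | None = None,
        beta_precision: float = 1e-3,
        psi_by_disease: bool = False,
        countries: Sequence[str] | None = None,
    ):
        unknown = set(components) - set(ALL_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)}")
        if graph is None:
            if any(c in components for c in ("lambda", "u")):
                raise ValueError("spatial components require an adjacency graph")
            if countries is None:
                raise ValueError("countries must be given when no graph is supplied")
        self.graph = graph
        self.countries = list(graph.nodes) if graph is not None else sorted(countries)
        self.diseases = sorted(diseases)
        self.years = sorted(int(y) for y in years)
        self.covariates = list(covariates)
        self.components = [c for c in ALL_COMPONENTS if c in components]
        if "beta" in self.components and not self.covariates:
            self.components.remove("beta")
        self.beta_precision = float(beta_precision)
        self.psi_by_disease = bool(psi_by_disease)

        self.I = len(self.countries)
        self.D = len(self.diseases)
        self.T = len(self.years)

        priors = dict(priors or {})
        self._priors_config = priors
        self.precision_priors: dict[str, PCPrecisionPrior] = {}
        for comp in ("alpha", "lambda", "u", "phi", "v", "psi"):
            cfg = {**DEFAULT_PRECISION_PRIOR, **priors.get(comp, {})}
            self.precision_priors[comp] = PCPrecisionPrior(cfg["U"], cfg["alpha"])

        # spatial / temporal structures, variance-scaled
        need_spatial = any(c in self.components for c in ("lambda", "u"))
        need_temporal = any(c in self.components for c in ("phi", "v"))
        self.icar_scaled: StructureMatrix | None = None
        self.rw1_scaled: StructureMatrix | None = None
        self.mixing_priors: dict[str, PCMixingPrior] = {}
        if need_spatial:
            self.icar_scaled = scale_structure(icar_structure(graph))
            for comp in ("lambda", "u"):
                if comp in self.components:
                    mix = {**DEFAULT_MIXING_PRIOR}
                    mix.update(
                        {
                            "U": priors.get(comp, {}).get("mixing_U", mix["U"]),
                            "alpha": priors.get(comp, {}).get("mixing_alpha", mix["alpha"]),
                        }
                    )
                    self.mixing_priors[comp] = PCMixingPrior(
                        self.icar_scaled, mix["U"], mix["alpha"]
                    )
        if need_temporal:
            self.rw1_scaled = scale_structure(rw1_structure(self.T))

        self._build_blocks()

    # ------------------------------------------------------------------
    def _build_blocks(self):
        I, D, T = self.I, self.D, self.T
        blocks: list[DenseBlock] = []

        def ones_row(size, idx_sets):
            C = np.zeros((len(idx_sets), size))
            for r, idx in enumerate(idx_sets):
                C[r, idx] = 1.0
            return C

        if "beta" in self.components:
            p = len(self.covariates)
            blocks.append(
                DenseBlock(
                    name="beta",
                    component="beta",
                    size=p,
                    C=None,
                    B=np.eye(p),
                    Q_fn=lambda h, p=p: self.beta_precision * np.eye(p),
                    design_fn=lambda panel: panel.covariate_matrix(),
                    z_names=[f"beta[{c}]" for c in self.covariates],
                )
            )
        if "alpha" in self.components:
            blocks.append(
                DenseBlock(
                    name="alpha",
                    component="alpha",
                    size=D,
                    C=None,
                    B=np.eye(D),
                    Q_fn=lambda h, D=D: h.tau_alpha * np.eye(D),
                    design_fn=lambda panel: np.eye(D)[panel.disease_idx],
                    z_names=[f"alpha[{d}]" for d in self.diseases],
                )
            )
        if "lambda" in self.components:
            C = ones_row(2 * I, [np.arange(I), np.arange(I, 2 * I)])
            blocks.append(
                DenseBlock(
                    name="lambda",
                    component="lambda",
                    size=2 * I,
                    C=C,
                    B=constraint_null_basis(C, 2 * I),
                    Q_fn=lambda h: bym2_joint_precision(
                        h.rho_lambda, h.tau_lambda, self.icar_scaled.Q
                    ),
                    design_fn=lambda panel: np.hstack(
                        [np.eye(I)[panel.country_idx], np.zeros((panel.n_rows, I))]
                    ),
                    z_names=[f"lambda[{c}]" for c in self.countries]
                    + [f"lambda_star[{c}]" for c in self.countries],
                )
            )
        if "u" in self.components:
            C = ones_row(2 * I, [np.arange(I), np.arange(I, 2 * I)])
            B = constraint_null_basis(C, 2 * I)
            for d_ix, d in enumerate(self.diseases):
                blocks.append(
                    DenseBlock(
                        name=f"u:{d}",
                        component="u",
                        size=2 * I,
                        C=C,
                        B=B,
                        Q_fn=lambda h: bym2_joint_precision(
                            h.rho_u, h.tau_u, self.icar_scaled.Q
                        ),
                        design_fn=lambda panel, d_ix=d_ix: np.hstack(
                            [
                                np.eye(I)[panel.country_idx]
                                * (panel.disease_idx == d_ix)[:, None],
                                np.zeros((panel.n_rows, I)),
                            ]
                        ),
                        z_names=[f"u[{d},{c}]" for c in self.countries]
                        + [f"u_star[{d},{c}]" for c in self.countries],
                    )
                )
        if "phi" in self.components:
            C = np.ones((1, T))
            blocks.append(
                DenseBlock(
                    name="phi",
                    component="phi",
                    size=T,
                    C=C,
                    B=constraint_null_basis(C, T),
                    Q_fn=lambda h: h.tau_phi * self.rw1_scaled.Q,
                    design_fn=lambda panel: np.eye(T)[panel.year_idx],
                    z_names=[f"phi[{y}]" for y in self.years],
                )
            )
        if "v" in self.components:
            C = np.ones((1, T))
            B = constraint_null_basis(C, T)
            for d_ix, d in enumerate(self.diseases):
                blocks.append(
                    DenseBlock(
                        name=f"v:{d}",
                        component="v",
                        size=T,
                        C=C,
                        B=B,
                        Q_fn=lambda h: h.tau_v * self.rw1_scaled.Q,
                        design_fn=lambda panel, d_ix=d_ix: np.eye(T)[panel.year_idx]
                        * (panel.disease_idx == d_ix)[:, None],
                        z_names=[f"v[{d},{y}]" for y in self.years],
                    )
                )
        self.dense_blocks = blocks
        self.has_psi = "psi" in self.components

        # slices into the dense z and w vectors
        z0 = w0 = 0
        self.z_slices: dict[str, slice] = {}
        self.w_slices: dict[str, slice] = {}
        for b in blocks:
            self.z_slices[b.name] = slice(z0, z0 + b.size)
            self.w_slices[b.name] = slice(w0, w0 + b.w_size)
            z0 += b.size
            w0 += b.w_size
        self.m_z = z0
        self.m_w = w0

    # -- hyperparameters -------------------------------------------------
    @property
    def hyper_names(self) -> list[str]:
        names = []
        if "alpha" in self.components:
            names.append("tau_alpha")
        if "lambda" in self.components:
            names += ["tau_lambda", "rho_lambda"]
        if "u" in self.components:
            names += ["tau_u", "rho_u"]
        if "phi" in self.components:
            names.append("tau_phi")
        if "v" in self.components:
            names.append("tau_v")
        if "psi" in self.components:
            if self.psi_by_disease:
                names += [f"tau_psi[{d}]" for d in self.diseases]
            else:
                names.append("tau_psi")
        return names

    def hyper_to_vector(self, h: Hyperparameters) -> np.ndarray:
        out = []
        for name in self.hyper_names:
            if name.startswith("tau_psi[") :
                d = name[len("tau_psi[") : -1]
                tau = np.broadcast_to(np.atleast_1d(h.tau_psi), (self.D,))
                out.append(float(tau[self.diseases.index(d)]))
            else:
                out.append(float(getattr(h, name)))
        return np.array(out)

    def hyper_from_vector(self, vec: np.ndarray) -> Hyperparameters:
        kw = {}
        psi_vals = {}
        for name, v in zip(self.hyper_names, vec):
            if name.startswith("tau_psi["):
                psi_vals[name[len("tau_psi[") : -1]] = float(v)
            else:
                kw[name] = float(v)
        if psi_vals:
            kw["tau_psi"] = np.array([psi_vals[d] for d in self.diseases])
        return Hyperparameters(**{**_HYPER_DEFAULTS, **kw})

    def hyper_transform(self, nat: np.ndarray) -> np.ndarray:
        """Map natural-scale hypers to the unconstrained sampling scale."""
        out = np.empty_like(np.asarray(nat, dtype=float))
        for k, name in enumerate(self.hyper_names):
            if name.startswith("rho"):
                out[k] = np.log(nat[k]) - np.log1p(-nat[k])
            else:
                out[k] = np.log(nat[k])
        return out

    def hyper_untransform(self, trans: np.ndarray) -> np.ndarray:
        out = np.empty_like(np.asarray(trans, dtype=float))
        for k, name in enumerate(self.hyper_names):
            if name.startswith("rho"):
                out[k] = 1.0 / (1.0 + np.exp(-trans[k]))
            else:
                out[k] = np.exp(trans[k])
        return out

    def hyper_log_jacobian(self, nat: np.ndarray) -> float:
        """log |d nat / d trans| for the transform above."""
        total = 0.0
        for k, name in enumerate(self.hyper_names):
            if name.startswith("rho"):
                total += np.log(nat[k]) + np.log1p(-nat[k])
            else:
                total += np.log(nat[k])
        return float(total)

    def hyper_logprior(self, h: Hyperparameters) -> float:
        """Sum of PC hyperprior log densities for all active components."""
        total = 0.0
        if "alpha" in self.components:
            total += float(self.precision_priors["alpha"].logpdf(h.tau_alpha))
        if "lambda" in self.components:
            total += float(self.precision_priors["lambda"].logpdf(h.tau_lambda))
            total += float(self.mixing_priors["lambda"].logpdf(np.clip(h.rho_lambda, 1e-12, 1 - 1e-12)))
        if "u" in self.components:
            total += float(self.precision_priors["u"].logpdf(h.tau_u))
            total += float(self.mixing_priors["u"].logpdf(np.clip(h.rho_u, 1e-12, 1 - 1e-12)))
        if "phi" in self.components:
            total += float(self.precision_priors["phi"].logpdf(h.tau_phi))
        if "v" in self.components:
            total += float(self.precision_priors["v"].logpdf(h.tau_v))
        if "psi" in self.components:
            taus = np.broadcast_to(np.atleast_1d(h.tau_psi), (self.D,)) if self.psi_by_disease else [
                float(np.atleast_1d(h.tau_psi)[0])
            ]
            for t in np.atleast_1d(taus):
                total += float(self.precision_priors["psi"].logpdf(t))
        return total

    # -- constraints -----------------------------------------------------
    def build_constraints(self) -> dict[str, np.ndarray]:
        """Constraint rows per dense block (``C z = 0``).

        Sum-to-zero over countries for the shared spatial effect and its
        structured half, the same per disease for the disease-specific
        fields, and sum-to-zero over years for each temporal trend.  Raises
        if a constraint direction is neither a null direction of the block's
        structure nor one of the explicit identifiability constraints.
        """
        out = {}
        for b in self.dense_blocks:
            if b.C is None:
                continue
            if b.component in ("phi", "v"):
                # must span the RW1 null space exactly
                Q = self.rw1_scaled.Q
                if np.abs(Q @ b.C.T).max() > 1e-8:
                    raise ConstraintViolationError(
                        f"constraint for {b.name} is not in the RW1 null space"
                    )
            out[b.name] = b.C.copy()
        return out

    # -- config ----------------------------------------------------------
    @classmethod
    def from_config(
        cls,
        config: dict | str,
        graph: CountryGraph | None = None,
        diseases: Sequence[str] | None = None,
        years: Sequence[int] | None = None,
        covariates: Sequence[str] | None = None,
    ) -> "ModelSpec":
        if isinstance(config, str):
            with open(config) as fh:
                config = yaml.safe_load(fh)
        mcfg = dict(config.get("model", config))
        gcfg = dict(config.get("graph", {}))
        if graph is None:
            kind = gcfg.get("kind", "eac")
            if kind == "eac":
                graph = build_eac_graph(bool(gcfg.get("include_lake_borders", False)))
            elif kind == "edge_csv":
                graph = CountryGraph.from_edge_csv(gcfg["path"])
            else:
                raise ValueError(f"unknown graph kind {kind!r}")
        return cls(
            graph=graph,
            diseases=diseases if diseases is not None else mcfg["diseases"],
            years=years if years is not None else mcfg["years"],
            covariates=covariates if covariates is not None else mcfg.get("covariates", []),
            components=mcfg.get("components", ALL_COMPONENTS),
            priors=mcfg.get("priors"),
            beta_precision=mcfg.get("beta_precision", 1e-3),
            psi_by_disease=mcfg.get("psi_by_disease", False),
        )


_HYPER_DEFAULTS = {f.name: f.default for f in dataclasses.fields(Hyperparameters)}
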