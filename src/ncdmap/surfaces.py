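"""Posterior effect surfaces: the fitted quantities the analysis reports.

Each latent component of the fitted model can be extracted as a tidy table
of posterior means and 95% credible intervals on the latent (log-risk)
scale — shared and disease-specific spatial effects, temporal curves, the
interaction — or, for ``"rr"``, the relative-risk surface ``theta_itd`` on
the exponential scale per (country, year, disease).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

_LABEL_COLS = {
    "lambda": ["country_id"],
    "lambda_star": ["country_id"],
    "u": ["disease", "country_id"],
    "u_star": ["disease", "country_id"],
    "phi": ["year"],
    "v": ["disease", "year"],
    "alpha": ["disease"],
    "beta": ["covariate"],
    "psi": ["disease", "country_id", "year"],
}

AVAILABLE_COMPONENTS = sorted(_LABEL_COLS) + ["rr"]


@dataclasses.dataclass
class EffectSurface:
    """Posterior mean and interval per cell of one latent component."""

    component: str
    table: pd.DataFrame  # label columns + mean, lo2.5, median, hi97.5

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, component: str) -> "EffectSurface":
        return cls(component=component, table=pd.read_csv(path))


def _summ(draws: np.ndarray) -> dict[str, np.ndarray]:
    q = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    return {"mean": draws.mean(axis=0), "lo2.5": q[0], "median": q[1], "hi97.5": q[2]}


def extract_effect(posterior, component: str) -> EffectSurface:
    """Tidy posterior surface for one component of a fitted model.

    ``component`` is one of the latent names (``lambda``, ``u``, ``phi``,
    ``v``, ``psi``, ``alpha``, ``beta``, plus the BYM2 structured halves
    ``lambda_star`` / ``u_star``) or ``"rr"`` for the relative-risk surface
    ``exp(eta)`` per observation cell.
    """
    if component == "rr":
        theta = np.exp(posterior.eta_draws)
        panel = posterior.panel
        tab = pd.DataFrame(
            {
                "country_id": panel.df["country_id"],
                "year": panel.df["year"],
                "disease": panel.df["disease"],
            }
        )
        for k, v in _summ(theta).items():
            tab[k] = v
        return EffectSurface("rr", tab)
    if component not in _LABEL_COLS:
        raise KeyError(
            f"unknown component {component!r}; available: {AVAILABLE_COMPONENTS}"
        )
    names, draws = posterior.draws_for(component + "[")
    if not names:
        raise KeyError(
            f"component {component!r} not present in this fit; available: "
            f"{sorted({n.split('[')[0] for n in posterior.z_names})}"
        )
    labels = [n[len(component) + 1 : -1].split(",") for n in names]
    tab = pd.DataFrame(labels, columns=_LABEL_COLS[component])
    if "year" in tab.columns:
        tab["year"] = tab["year"].astype(int)
    for k, v in _summ(draws).items():
        tab[k] = v
    return EffectSurface(component, tab)
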