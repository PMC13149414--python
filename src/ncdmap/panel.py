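"""Mortality panel ingestion, validation, standardization and expected deaths.

The analysis operates on a balanced long-format panel of
(country, year, disease) observations.  Each row carries the observed death
count ``Y_itd``, the population ``P_it``, the age-standardized mortality rate
``R_itd`` (deaths per 100,000) and one column per contextual covariate.
Covariates vary by country and year only, never by disease.

Expected deaths are the standardization offset of the relative-risk model::

    E_itd = P_it * R_itd / 100_000

so that the relative mortality risk ``theta = Y / E`` equals 1 when observed
mortality matches the age-standardized expectation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical covariate roster (environmental + socioeconomic determinants)
COVARIATES = [
    "ndvi",
    "temperature",
    "precipitation",
    "gdp_pc",
    "health_exp",
    "urbanization",
    "pop_density",
    "pm25",
]

REQUIRED_COLUMNS = ["country_id", "year", "disease", "deaths", "population", "asmr"]


class PanelValidationError(ValueError):
    """Raised when a panel violates its structural invariants.

    Attributes
    ----------
    report : list of str
        Itemized description of every violation found.
    """

    def __init__(self, report: Sequence[str]):
        self.report = list(report)
        super().__init__(
            "panel validation failed:\n" + "\n".join(f"  - {r}" for r in self.report)
        )


def compute_expected_deaths(population, asmr):
    """Expected deaths ``E = P * R / 100_000`` for each panel row.

    Parameters
    ----------
    population : array-like
        Person counts ``P_it``; must be strictly positive.
    asmr : array-like
        Age-standardized mortality rate per 100,000, ``R_itd``; non-negative.

    Returns
    -------
    ndarray
        ``E_itd``, zero exactly where the rate is zero.
    """
    P = np.asarray(population, dtype=float)
    R = np.asarray(asmr, dtype=float)
    bad_p = np.flatnonzero(~(P > 0))
    bad_r = np.flatnonzero(R < 0)
    problems = []
    if bad_p.size:
        problems.append(f"non-positive population at rows {bad_p[:10].tolist()}")
    if bad_r.size:
        problems.append(f"negative asmr at rows {bad_r[:10].tolist()}")
    if problems:
        raise PanelValidationError(problems)
    return P * R / 100_000.0


@dataclasses.dataclass
class StandardizationRecord:
    """Per-covariate moments used for z-scoring (sample sd, denominator n-1)."""

    table: pd.DataFrame  # columns: covariate, mean, sd

    def __post_init__(self):
        if (self.table["sd"] <= 0).any():
            bad = self.table.loc[self.table["sd"] <= 0, "covariate"].tolist()
            raise ValueError(f"non-positive sd recorded for covariates {bad}")

    @property
    def covariates(self) -> list[str]:
        return self.table["covariate"].tolist()

    def mean(self, name: str) -> float:
        return float(self.table.set_index("covariate").loc[name, "mean"])

    def sd(self, name: str) -> float:
        return float(self.table.set_index("covariate").loc[name, "sd"])

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for _, row in self.table.iterrows():
            out[row["covariate"]] = (df[row["covariate"]] - row["mean"]) / row["sd"]
        return out

    def unstandardize_coef(self, name: str, beta_std: float) -> float:
        """Map a coefficient on the z-scored scale back to the raw scale."""
        return beta_std / self.sd(name)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StandardizationRecord":
        return cls(pd.read_csv(path))


@dataclasses.dataclass
class VifReport:
    """Variance inflation factors, flagged at the conventional threshold of 5."""

    table: pd.DataFrame  # columns: covariate, vif, flagged
    threshold: float = 5.0

    @property
    def any_flagged(self) -> bool:
        return bool(self.table["flagged"].any())

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


class MortalityPanel:
    """Validated balanced panel in canonical (disease, country, year) order.

    Do not construct directly from raw data; use :func:`validate_panel`.

    The canonical order is disease-major, then country, then year, so that a
    flat vector indexed by panel row maps deterministically onto the latent
    components of the risk model.
    """

    def __init__(self, df: pd.DataFrame, covariates: Sequence[str]):
        self.df = df.reset_index(drop=True)
        self.covariates = list(covariates)
        self.countries = sorted(df["country_id"].unique().tolist())
        self.diseases = sorted(df["disease"].unique().tolist())
        self.years = sorted(int(y) for y in df["year"].unique())
        self.n_countries = len(self.countries)
        self.n_diseases = len(self.diseases)
        self.n_years = len(self.years)
        c_pos = {c: k for k, c in enumerate(self.countries)}
        d_pos = {d: k for k, d in enumerate(self.diseases)}
        y_pos = {y: k for k, y in enumerate(self.years)}
        self.country_idx = self.df["country_id"].map(c_pos).to_numpy()
        self.disease_idx = self.df["disease"].map(d_pos).to_numpy()
        self.year_idx = self.df["year"].map(y_pos).to_numpy()

    # -- array views ------------------------------------------------------
    @property
    def y(self) -> np.ndarray:
        return self.df["deaths"].to_numpy(dtype=float)

    @property
    def expected(self) -> np.ndarray:
        return self.df["expected_deaths"].to_numpy(dtype=float)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def covariate_matrix(self) -> np.ndarray:
        """Row-aligned covariate matrix (one row per panel observation)."""
        return self.df[self.covariates].to_numpy(dtype=float)

    def cell_table(self) -> pd.DataFrame:
        """One row per unique (country, year) cell, with covariates."""
        cols = ["country_id", "year", "population"] + self.covariates
        return (
            self.df[cols]
            .drop_duplicates(subset=["country_id", "year"])
            .sort_values(["country_id", "year"])
            .reset_index(drop=True)
        )

    def to_csv(self, path):
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, covariates: Sequence[str] | None = None) -> "MortalityPanel":
        return validate_panel(pd.read_csv(path), covariates=covariates)

    def copy_with(self, df: pd.DataFrame) -> "MortalityPanel":
        return MortalityPanel(df, self.covariates)


def _detect_covariates(df: pd.DataFrame) -> list[str]:
    known = set(REQUIRED_COLUMNS) | {"expected_deaths"}
    return [c for c in df.columns if c not in known]


def validate_panel(
    df: pd.DataFrame, covariates: Sequence[str] | None = None
) -> MortalityPanel:
    """Check balance, count integrality and covariate constancy; sort canonically.

    Returns a :class:`MortalityPanel` in disease-major canonical order, with
    ``expected_deaths`` computed from population and asmr when absent.

    Raises
    ------
    PanelValidationError
        With an itemized report of every violated invariant.
    """
    report: list[str] = []
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelValidationError([f"missing required columns {missing_cols}"])
    if covariates is None:
        covariates = _detect_covariates(df)
    for c in covariates:
        if c not in df.columns:
            report.append(f"missing covariate column {c!r}")
    if report:
        raise PanelValidationError(report)

    df = df.copy()
    df["year"] = df["year"].astype(int)

    deaths = df["deaths"].to_numpy(dtype=float)
    if np.any(deaths < 0):
        report.append("negative death counts present")
    nonint = np.flatnonzero(np.abs(deaths - np.round(deaths)) > 1e-9)
    if nonint.size:
        report.append(f"non-integer death counts at rows {nonint[:10].tolist()}")
    if np.any(~(df["population"].to_numpy(dtype=float) > 0)):
        report.append("non-positive population present")
    if np.any(df["asmr"].to_numpy(dtype=float) < 0):
        report.append("negative asmr present")

    countries = sorted(df["country_id"].unique().tolist())
    diseases = sorted(df["disease"].unique().tolist())
    years = sorted(int(y) for y in df["year"].unique())
    if len(years) >= 2 and years != list(range(years[0], years[-1] + 1)):
        report.append(f"years are not consecutive: {years}")

    # balance: every (i, t, d) combination exactly once
    key = pd.MultiIndex.from_frame(df[["disease", "country_id", "year"]])
    dup = key[key.duplicated()]
    if len(dup):
        report.append(f"duplicate rows for cells {list(dup[:5])}")
    full = pd.MultiIndex.from_product(
        [diseases, countries, years], names=["disease", "country_id", "year"]
    )
    missing = full.difference(key)
    if len(missing):
        report.append(f"missing (disease, country, year) cells: {list(missing[:5])}")

    # covariate (and population) constancy across diseases within (i, t)
    const_cols = list(covariates) + ["population"]
    g = df.groupby(["country_id", "year"], sort=False)
    for col in const_cols:
        spread = g[col].agg(lambda s: float(np.max(s) - np.min(s)))
        bad = spread[spread.abs() > 1e-9 * (1.0 + spread.abs().max())]
        if len(bad):
            cell = bad.index[0]
            report.append(
                f"column {col!r} varies across diseases within cell "
                f"(country={cell[0]}, year={cell[1]})"
            )

    if report:
        raise PanelValidationError(report)

    df["deaths"] = np.round(deaths).astype(int)
    if "expected_deaths" not in df.columns:
        df["expected_deaths"] = compute_expected_deaths(df["population"], df["asmr"])
    if np.any(~(df["expected_deaths"].to_numpy(dtype=float) > 0)):
        raise PanelValidationError(
            ["expected_deaths must be strictly positive (zero asmr row present?)"]
        )

    df = df.sort_values(["disease", "country_id", "year"], kind="mergesort")
    ordered = REQUIRED_COLUMNS + ["expected_deaths"] + list(covariates)
    return MortalityPanel(df[ordered], covariates)


def standardize_covariates(
    panel: MortalityPanel,
) -> tuple[MortalityPanel, StandardizationRecord]:
    """Z-score every covariate over the unique (country, year) cells.

    Moments are computed over the I x T cells rather than the replicated
    disease rows, so that each cell contributes once regardless of how many
    diseases are modeled.  Sample sd (denominator n-1) is used and recorded.
    """
    cells = panel.cell_table()
    rows = []
    for c in panel.covariates:
        x = cells[c].to_numpy(dtype=float)
        m = float(np.mean(x))
        s = float(np.std(x, ddof=1))
        if not s > 1e-12 * max(1.0, abs(m)):
            raise ValueError(f"covariate {c!r} has (near-)zero variance; cannot standardize")
        rows.append({"covariate": c, "mean": m, "sd": s})
    record = StandardizationRecord(pd.DataFrame(rows))
    return panel.copy_with(record.transform(panel.df)), record


def compute_vif(X, names: Iterable[str] | None = None, threshold: float = 5.0) -> VifReport:
    """Variance inflation factors, one per column of ``X``.

    ``VIF_j = 1 / (1 - R^2_j)`` where ``R^2_j`` is from regressing column j on
    all other columns plus an intercept.  Perfectly collinear columns are
    reported as infinite and flagged rather than raising.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs a matrix with at least two covariates")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations (unique cells) than covariates")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    rows = []
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst <= 0:
            vif = np.inf
        else:
            frac = float(np.sum(resid**2)) / sst
            vif = np.inf if frac < 1e-12 else 1.0 / frac
        rows.append({"covariate": names[j], "vif": vif, "flagged": bool(vif >= threshold)})
    return VifReport(pd.DataFrame(rows), threshold=threshold)


def vif_from_panel(panel: MortalityPanel, standardized: bool = True) -> VifReport:
    """Collinearity screen on the unique-cell covariate matrix."""
    if standardized:
        panel, _ = standardize_covariates(panel)
    cells = panel.cell_table()
    return compute_vif(cells[panel.covariates].to_numpy(dtype=float), panel.covariates)
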