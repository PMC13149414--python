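"""End-to-end pipeline: validate -> standardize -> VIF -> fit -> diagnose -> export.

Driven by a single YAML/dict configuration; every run writes a manifest
(seed, config hash, version, stage timings) and a structured log so results
can be traced and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diagnostics import run_diagnostics
from .graphs import CountryGraph, build_eac_graph
from .inference import InferenceConfig, sample_hyperparameters
from .modelspec import ModelSpec
from .panel import standardize_covariates, vif_from_panel
from .simulate import SimulationConfig, simulate_panel
from .surfaces import extract_effect


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


DEFAULT_CONFIG = {
    "seed": 20_000,
    "data": {"simulate": True},
    "graph": {"kind": "eac", "include_lake_borders": False},
    "model": {},
    "inference": {"iterations": 1200, "burn_in": 400, "thin": 4},
    "output": {"directory": "ncdmap_run", "plots": False},
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _build_graph(gcfg: dict) -> CountryGraph:
    kind = gcfg.get("kind", "eac")
    if kind == "eac":
        return build_eac_graph(bool(gcfg.get("include_lake_borders", False)))
    if kind == "edge_csv":
        return CountryGraph.from_edge_csv(gcfg["path"])
    raise ValueError(f"unknown graph kind {kind!r}")


def run_pipeline(config=None, seed: int | None = None, outdir=None, verbose: bool = False) -> Path:
    """Run the full analysis; returns the artifact directory.

    ``seed`` overrides the config seed; ``outdir`` overrides the configured
    output directory.  Any stage failure aborts with the stage name.
    """
    cfg = _load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(outdir or cfg["output"]["directory"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "surfaces").mkdir(exist_ok=True)

    log: list[str] = []
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t = time.time()
                msg = f"[{name}] start"
                log.append(msg)
                if verbose:
                    print(msg)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.time() - self_inner.t
                if exc is not None:
                    log.append(f"[{name}] FAILED: {exc}")
                    (out / "log.txt").write_text("\n".join(log) + "\n")
                    raise PipelineError(name, exc) from exc
                msg = f"[{name}] done in {timings[name]:.2f}s"
                log.append(msg)
                if verbose:
                    print(msg)
                return False

        return _Stage()

    graph = _build_graph(cfg["graph"])
    truth = None
    with stage("load"):
        dcfg = cfg["data"]
        if dcfg.get("simulate", False):
            sim_kw = {k: v for k, v in dcfg.items() if k not in ("simulate", "panel_csv")}
            sim = SimulationConfig(seed=cfg["seed"], graph=graph, **sim_kw)
            panel, truth = simulate_panel(sim)
            raw_df = panel.df
            panel.to_csv(out / "panel.csv")
        else:
            raw_df = pd.read_csv(dcfg["panel_csv"])
            log.append(f"loaded panel from {dcfg['panel_csv']}")

    with stage("validate"):
        from .panel import validate_panel

        panel = validate_panel(raw_df)
        log.append(
            f"panel: {panel.n_countries} countries x {panel.n_diseases} diseases "
            f"x {panel.n_years} years = {panel.n_rows} rows"
        )

    with stage("standardize"):
        panel_std, record = standardize_covariates(panel)
        record.to_csv(out / "standardization.csv")

    with stage("vif"):
        vif = vif_from_panel(panel)
        vif.to_csv(out / "vif.csv")
        if vif.any_flagged:
            log.append("WARNING: covariates flagged at VIF >= 5")

    with stage("fit"):
        spec = ModelSpec.from_config(
            {"model": cfg["model"]},
            graph=graph,
            diseases=panel.diseases,
            years=panel.years,
            covariates=panel.covariates,
        )
        if truth is not None:
            truth.to_csv(out / "ground_truth.csv", spec)
        icfg = InferenceConfig(seed=cfg["seed"], **cfg["inference"])
        posterior = sample_hyperparameters(panel_std, spec, icfg)
        posterior.summary("main").to_csv(out / "summary_main.csv", index=False)
        posterior.to_csv(out / "draws.csv")

    with stage("diagnose"):
        report = run_diagnostics(panel_std, posterior)
        report.to_csv(out / "diagnostics.csv", out / "diagnostics_rows.csv")

    with stage("extract"):
        for comp in ("lambda", "u", "phi", "v", "alpha", "beta", "rr"):
            try:
                extract_effect(posterior, comp).to_csv(out / "surfaces" / f"{comp}.csv")
            except KeyError:
                pass  # component not in this model configuration

    if cfg["output"].get("plots", False):
        with stage("plots"):
            _diagnostic_plots(out, panel, posterior, report)

    with stage("manifest"):
        blob = yaml.safe_dump(cfg, sort_keys=True).encode()
        manifest = {
            "seed": cfg["seed"],
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "version": __version__,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "acceptance_rate": posterior.metadata["acceptance_rate"],
            "n_draws": posterior.n_draws,
            "warnings": posterior.metadata["warnings"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    (out / "log.txt").write_text("\n".join(log) + "\n")
    return out


def _diagnostic_plots(out: Path, panel, posterior, report):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.hist(report.pit, bins=20, range=(0, 1), color="steelblue", edgecolor="white")
    ax.axhline(len(report.pit) / 20, color="k", ls="--", lw=1)
    ax.set(xlabel="PIT", ylabel="count", title="Leave-one-out PIT")
    fig.savefig(out / "pit_hist.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.loglog(report.fitted["observed"] + 1, report.fitted["fitted_mean"] + 1, ".", ms=3)
    lims = ax.get_xlim()
    ax.plot(lims, lims, "k--", lw=1)
    ax.set(xlabel="observed + 1", ylabel="fitted mean + 1", title="Observed vs fitted")
    fig.savefig(out / "observed_vs_fitted.png", dpi=120)
    plt.close(fig)

    from .surfaces import extract_effect

    fig, ax = plt.subplots()
    try:
        phi = extract_effect(posterior, "phi").table
        yrs = phi["year"].astype(int)
        ax.plot(yrs, phi["mean"], label="shared phi")
        ax.fill_between(yrs, phi["lo2.5"], phi["hi97.5"], alpha=0.25)
    except KeyError:
        pass
    ax.set(xlabel="year", ylabel="temporal effect (log scale)", title="Shared temporal trend")
    ax.legend()
    fig.savefig(out / "temporal_effects.png", dpi=120)
    plt.close(fig)
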